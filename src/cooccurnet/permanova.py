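"""One-way PERMANOVA on labeled distance matrices.

Implements the permutational multivariate analysis of variance of
Anderson (2001): sums of squared interpoint distances are partitioned into
within- and between-group components,

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    pseudo-F  = [SS_between / (a-1)] / [SS_within / (N-a)]

and the pseudo-F is referred to its permutation distribution under random
relabeling of whole objects. Used both for the Spearman-distance
co-occurrence test and the Bray-Curtis composition test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sympy.utilities.iterables import multiset_permutations

from .correlate import DistanceMatrix

__all__ = ["PermanovaResult", "permanova", "permanova_exact",
           "permanova_null_calibration"]


@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p: float
    n_permutations: int
    group_sizes: dict[str, int]
    seed: int


def _decompose(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss_total, ss_within


def _pseudo_f(ss_total: float, ss_within: float, n: int, a: int) -> float:
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    dm: DistanceMatrix, n_permutations: int = 9999, seed: int = 0
) -> PermanovaResult:
    """One-way PERMANOVA with the group labels carried by the matrix.

    The p-value uses the ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)``
    convention, so p is never 0 and permutation ties count against the null.
    """
    labels = dm.group_labels()
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    n = len(labels)
    if a < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    sizes = {str(u): int((codes == i).sum()) for i, u in enumerate(uniq)}
    small = [g for g, s in sizes.items() if s < 2]
    if small:
        raise ValueError(f"groups with < 2 objects: {small}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    d2 = dm.d.astype(float) ** 2
    ss_total, ss_within = _decompose(d2, codes, a)
    f_obs = _pseudo_f(ss_total, ss_within, n, a)
    r2 = 0.0 if ss_total == 0 else (ss_total - ss_within) / ss_total

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm_codes = codes[rng.permutation(n)]
        _, ss_w = _decompose(d2, perm_codes, a)
        f_perm = _pseudo_f(ss_total, ss_w, n, a)
        if f_perm >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(r2), float(p),
                           n_permutations, sizes, seed)


def permanova_exact(dm: DistanceMatrix) -> PermanovaResult:
    """PERMANOVA with the p-value from exhaustive enumeration of all distinct
    group relabelings (feasible only for small N); p = #{F >= F_obs} / total,
    the observed labeling included.
    """
    labels = dm.group_labels()
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    n = len(labels)
    if a < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    d2 = dm.d.astype(float) ** 2
    ss_total, ss_within = _decompose(d2, codes, a)
    f_obs = _pseudo_f(ss_total, ss_within, n, a)
    r2 = 0.0 if ss_total == 0 else (ss_total - ss_within) / ss_total
    hits = 0
    total = 0
    for relab in multiset_permutations(codes.tolist()):
        _, ss_w = _decompose(d2, np.asarray(relab), a)
        if _pseudo_f(ss_total, ss_w, n, a) >= f_obs - 1e-12:
            hits += 1
        total += 1
    sizes = {str(u): int((codes == i).sum()) for i, u in enumerate(uniq)}
    return PermanovaResult(float(f_obs), float(r2), hits / total, total - 1,
                           sizes, 0)


def permanova_null_calibration(
    generator_config,
    n_runs: int,
    alpha: float,
    seed: int,
    n_permutations: int = 999,
) -> float:
    """Empirical rejection rate of the Spearman-distance PERMANOVA pipeline.

    Repeats simulate -> Spearman distance -> PERMANOVA ``n_runs`` times with
    fresh seeds derived from ``seed`` and returns the fraction of runs with
    p <= alpha. With a null (independent-taxa) configuration this estimates
    the type-I error rate, which should sit near the nominal alpha.
    """
    from .simulate import simulate_study
    from .correlate import spearman_distance_matrix

    ss = np.random.SeedSequence(seed)
    rejections = 0
    for child in ss.spawn(n_runs):
        s1, s2 = child.generate_state(2) % (2**31)
        cfg = replace(generator_config, seed=int(s1))
        study = simulate_study(cfg)
        dm = spearman_distance_matrix(study)
        res = permanova(dm, n_permutations=n_permutations, seed=int(s2))
        if res.p <= alpha:
            rejections += 1
    return rejections / n_runs
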