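"""Pairwise Spearman correlations and labeled distance matrices.

Co-occurrence between two taxa is measured by Spearman's rank correlation
of their abundances across the samples of one replicate group. Two distance
constructions are provided:

* the community-scale *Spearman distance* matrix, ``d = 1 - rho``, whose
  objects are (taxon, ecosystem, replicate) abundance profiles — small
  distances mean strong positive co-occurrence; and
* the classical Bray-Curtis dissimilarity between samples, used to test
  for compositional differences between ecosystems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceStudy

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationSet",
    "DistanceMatrix",
    "replicate_correlations",
    "spearman_distance_matrix",
    "bray_curtis_matrix",
]


@dataclass
class CorrelationSet:
    """All pairwise Spearman correlations within one replicate.

    ``pairs`` maps lexicographically ordered taxon pairs ``(a, b)``, a < b,
    to ``(rho, p, n)``. Pairs involving a taxon with all-zero abundance in
    the replicate, or an undefined (constant-vector) correlation, are absent.
    """

    ecosystem: str
    replicate: str
    pairs: dict[tuple[str, str], tuple[float, float, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "taxon_a": a,
                "taxon_b": b,
                "rho": rho,
                "p": p,
                "n": n,
                "ecosystem": self.ecosystem,
                "replicate": self.replicate,
            }
            for (a, b), (rho, p, n) in sorted(self.pairs.items())
        ]
        return pd.DataFrame(
            rows, columns=["taxon_a", "taxon_b", "rho", "p", "n",
                           "ecosystem", "replicate"]
        )


@dataclass
class DistanceMatrix:
    """A symmetric labeled distance matrix with a grouping for PERMANOVA."""

    object_ids: list[str]
    d: np.ndarray
    metric_name: str
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.object_ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    def group_labels(self) -> np.ndarray:
        return np.array([self.groups[o] for o in self.object_ids])

    def write(self, matrix_path, groups_path) -> None:
        frame = pd.DataFrame(self.d, index=self.object_ids, columns=self.object_ids)
        frame.index.name = "object_id"
        frame.to_csv(matrix_path, sep="\t")
        pd.DataFrame(
            {"object_id": self.object_ids,
             "group": [self.groups[o] for o in self.object_ids]}
        ).to_csv(groups_path, sep="\t", index=False)

    @classmethod
    def read(cls, matrix_path, groups_path, metric_name: str = "unknown"):
        frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t", dtype=str)
        mapping = dict(zip(groups["object_id"], groups["group"]))
        return cls([str(i) for i in frame.index], frame.to_numpy(),
                   metric_name, mapping)


def replicate_correlations(
    study: AbundanceStudy, ecosystem: str, replicate: str
) -> CorrelationSet:
    """Spearman rho (average ranks for ties) for every taxon pair in one
    replicate, with the two-sided t-approximation p-value.

    Requires >= 3 samples; taxa with all-zero abundance in the replicate are
    excluded, as are pairs where either vector is constant (rho undefined).
    """
    idx = study.sample_indices(ecosystem, replicate)
    if idx.size == 0:
        raise ValueError(f"no samples for ({ecosystem!r}, {replicate!r})")
    if idx.size < 3:
        raise ValueError(
            f"replicate {replicate!r} has {idx.size} samples; >= 3 required "
            "for correlation inference"
        )
    sub = study.counts[:, idx]
    present = np.flatnonzero(sub.sum(axis=1) > 0)
    out = CorrelationSet(ecosystem=ecosystem, replicate=replicate)
    n = idx.size
    n_skipped = 0
    for ai in range(len(present)):
        for bi in range(ai + 1, len(present)):
            i, j = present[ai], present[bi]
            x, y = sub[i], sub[j]
            if np.all(x == x[0]) or np.all(y == y[0]):
                n_skipped += 1
                continue
            rho, p = stats.spearmanr(x, y)
            if not np.isfinite(rho):  # pragma: no cover - guarded above
                n_skipped += 1
                continue
            a, b = sorted((study.taxon_ids[i], study.taxon_ids[j]))
            out.pairs[(a, b)] = (float(rho), float(p), n)
    if n_skipped:
        logger.info(
            "replicate_correlations(%s/%s): %d constant-vector pairs excluded",
            ecosystem, replicate, n_skipped,
        )
    return out


def _rank_rows(mat: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, mat.astype(float))


def spearman_distance_matrix(study: AbundanceStudy) -> DistanceMatrix:
    """Community-scale distance matrix ``1 - rho`` over taxon profiles.

    One object per (taxon, ecosystem, replicate); its profile is the taxon's
    abundance vector over that replicate's samples, aligned by within-
    replicate sample position. All replicates must therefore contain the same
    number of samples. Objects are grouped by ecosystem, so a PERMANOVA on
    this matrix asks whether co-occurrence structure differs by ecosystem.

    Constant profiles have no defined rank correlation; their distances are
    set to 1 (rho = 0, the null expectation) with a logged warning.
    """
    blocks: list[np.ndarray] = []
    ids: list[str] = []
    groups: dict[str, str] = {}
    sizes: dict[str, int] = {}
    for eco in study.ecosystems():
        for rep in study.replicates(eco):
            idx = study.sample_indices(eco, rep)
            sizes[f"{eco}/{rep}"] = idx.size
            blocks.append(study.counts[:, idx])
            for taxon in study.taxon_ids:
                oid = f"{taxon}|{eco}|{rep}"
                ids.append(oid)
                groups[oid] = eco
    if len(set(sizes.values())) > 1:
        raise ValueError(
            f"unbalanced replicate sample counts: {sizes}; "
            "subsample to a balanced design first"
        )
    profiles = np.vstack(blocks)
    ranks = _rank_rows(profiles)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "spearman_distance_matrix: %d constant profiles; their distances "
            "set to 1", int(constant.sum()),
        )
    # corrcoef of ranks == Spearman rho; guard zero-variance rows
    safe = ranks.copy()
    safe[constant] = np.arange(ranks.shape[1])  # placeholder, overwritten below
    rho = np.corrcoef(safe)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return DistanceMatrix(ids, d, "spearman_distance", groups)


def bray_curtis_matrix(study: AbundanceStudy, scale: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    With ``scale=True`` each taxon row is min-max scaled to [0, 1] first
    (vegan's ``decostand(method="range")``), so abundant and rare taxa weigh
    equally. ``d(x, y) = sum|x_i - y_i| / sum(x_i + y_i)``; a pair of
    all-zero profiles is defined as distance 0 with a warning.
    """
    if len(study.sample_ids) < 2:
        raise ValueError("Bray-Curtis needs >= 2 samples")
    mat = study.counts.astype(float)
    if scale:
        lo = mat.min(axis=1, keepdims=True)
        rng_ = mat.max(axis=1, keepdims=True) - lo
        rng_[rng_ == 0] = 1.0
        mat = (mat - lo) / rng_
    x = mat.T  # samples x taxa
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    zero = den == 0
    if zero.sum() > len(x):  # off-diagonal zero-denominator pairs
        logger.warning("bray_curtis_matrix: all-zero sample pairs set to d=0")
    den[zero] = 1.0
    d = num / den
    d[zero] = 0.0
    np.fill_diagonal(d, 0.0)
    groups = {s: study.sample_meta[s][0] for s in study.sample_ids}
    return DistanceMatrix(list(study.sample_ids), d, "bray_curtis", groups)
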