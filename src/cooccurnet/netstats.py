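"""Node/network statistics and keystone ranking.

Per-node statistics are normalized degree (degree / (n-1)) and unnormalized
shortest-path betweenness (endpoints excluded, fractional credit over tied
shortest paths). At the network level the global clustering coefficient
(transitivity) is compared with the Erdos-Renyi expectation mean_degree/n to
flag small-world structure.

The degree-betweenness relationship is modeled as a power function

    betweenness = alpha * degree_norm^beta

fit on the log-log scale as a linear mixed model with a random intercept
per replicate, since each replicate network contributes its own node
observations. Keystone taxa are those with the highest betweenness
predicted by the fixed effects of this model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .network import CooccurrenceNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "NodeStats",
    "PowerFit",
    "NetworkSummary",
    "node_stats",
    "transitivity",
    "fit_power_mixed",
    "rank_keystones",
]


@dataclass
class NodeStats:
    taxon: str
    ecosystem: str
    replicate: str  # a replicate label, or "consensus"
    degree_norm: float
    betweenness: float
    level: float


@dataclass
class PowerFit:
    alpha: float
    beta: float
    beta_p: float
    random_intercepts: dict[str, float]
    n_obs: int
    ecosystem: str
    level: float
    n_excluded_zero: int = 0

    def predict(self, degree_norm: float) -> float:
        """Fixed-effects prediction alpha * x^beta."""
        return self.alpha * degree_norm**self.beta


@dataclass
class NetworkSummary:
    ecosystem: str
    sign: str
    level: float
    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    random_expectation: float
    small_world: bool


def node_stats(
    net: CooccurrenceNetwork, replicate: str = "consensus", level: float = 0.5
) -> list[NodeStats]:
    """Normalized degree and betweenness for every node of one network."""
    g = net.graph
    n = g.number_of_nodes()
    bet = nx.betweenness_centrality(g, normalized=False)
    out = []
    for node in sorted(g.nodes):
        dn = 0.0 if n <= 1 else g.degree[node] / (n - 1)
        out.append(
            NodeStats(node, net.ecosystem, replicate, float(dn),
                      float(bet[node]), level)
        )
    return out


def stats_frame(stats: list[NodeStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"taxon": s.taxon, "ecosystem": s.ecosystem, "replicate": s.replicate,
             "level": s.level, "degree_norm": s.degree_norm,
             "betweenness": s.betweenness}
            for s in stats
        ]
    )


def transitivity(net: CooccurrenceNetwork, level: float = 0.5) -> NetworkSummary:
    """Global transitivity (3 x triangles / connected triples) plus the
    random-graph expectation and the resulting small-world flag."""
    g = net.graph
    n = g.number_of_nodes()
    m = g.number_of_edges()
    triples = sum(d * (d - 1) // 2 for _, d in g.degree)
    if triples == 0:
        logger.warning("transitivity: no connected triples; defined as 0")
        cc = 0.0
    else:
        cc = float(nx.transitivity(g))
    mean_degree = 0.0 if n == 0 else 2.0 * m / n
    rand_exp = 0.0 if n == 0 else mean_degree / n
    return NetworkSummary(
        net.ecosystem, net.sign, level, n, m, cc, rand_exp, cc > rand_exp
    )


def fit_power_mixed(
    stats: list[NodeStats], ecosystem: str, level: float
) -> PowerFit:
    """Fit betweenness = alpha * degree_norm^beta across replicate networks.

    Linearized as ``log(bet) = log(alpha) + beta*log(deg) + u_rep + eps``
    with a Gaussian random intercept per replicate. Nodes with zero
    betweenness or zero degree carry no information on the log scale and are
    excluded; their count is recorded. With a single replicate (or a
    degenerate mixed fit) an ordinary least-squares fit is used instead,
    with a logged warning.
    """
    rows = [
        s for s in stats
        if s.ecosystem == ecosystem and s.level == level
    ]
    usable = [s for s in rows if s.betweenness > 0 and s.degree_norm > 0]
    n_excl = len(rows) - len(usable)
    if not usable:
        raise ValueError(
            f"degenerate network: no nodes with positive betweenness for "
            f"{ecosystem!r} at level {level}"
        )
    if len(usable) < 5:
        raise ValueError(
            f"too few usable nodes ({len(usable)}) for the power fit; >= 5 required"
        )
    df = pd.DataFrame(
        {
            "log_bet": np.log([s.betweenness for s in usable]),
            "log_deg": np.log([s.degree_norm for s in usable]),
            "replicate": [s.replicate for s in usable],
        }
    )
    n_reps = df["replicate"].nunique()
    intercepts: dict[str, float] = {}
    if n_reps >= 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm("log_bet ~ log_deg", df, groups=df["replicate"])
                fit = model.fit(reml=True, method=["lbfgs", "powell"])
            params = fit.fe_params
            alpha = float(np.exp(params["Intercept"]))
            beta = float(params["log_deg"])
            beta_p = float(fit.pvalues["log_deg"])
            try:
                intercepts = {
                    str(k): float(np.asarray(v).ravel()[0])
                    for k, v in fit.random_effects.items()
                }
            except (np.linalg.LinAlgError, ValueError):
                # replicate variance estimated at the zero boundary: BLUPs
                # are undefined, deviations are effectively zero
                intercepts = {str(r): 0.0 for r in df["replicate"].unique()}
            return PowerFit(alpha, beta, beta_p, intercepts, len(df),
                            ecosystem, level, n_excl)
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("mixed fit failed (%s); falling back to OLS", exc)
    else:
        logger.warning(
            "fit_power_mixed: single replicate for %s; ordinary regression used",
            ecosystem,
        )
    ols = sm.OLS(df["log_bet"], sm.add_constant(df["log_deg"])).fit()
    alpha = float(np.exp(ols.params["const"]))
    beta = float(ols.params["log_deg"])
    beta_p = float(ols.pvalues["log_deg"])
    return PowerFit(alpha, beta, beta_p, intercepts, len(df),
                    ecosystem, level, n_excl)


def rank_keystones(
    fit: PowerFit, stats: list[NodeStats], k: int = 3
) -> list[tuple[str, float]]:
    """Top-k taxa by fixed-effects predicted betweenness.

    A taxon observed in several replicates is summarized by its mean
    normalized degree (and mean observed betweenness for tie-breaking);
    remaining ties break by name. If k exceeds the number of taxa the full
    ranking is returned with a warning.
    """
    rows = [
        s for s in stats
        if s.ecosystem == fit.ecosystem and s.level == fit.level
    ]
    if not rows:
        raise ValueError("no node statistics match the fit's ecosystem/level")
    by_taxon: dict[str, list[NodeStats]] = {}
    for s in rows:
        by_taxon.setdefault(s.taxon, []).append(s)
    ranked = []
    for taxon, obs in by_taxon.items():
        mean_deg = float(np.mean([o.degree_norm for o in obs]))
        mean_bet = float(np.mean([o.betweenness for o in obs]))
        pred = fit.predict(mean_deg) if mean_deg > 0 else 0.0
        ranked.append((taxon, pred, mean_bet))
    ranked.sort(key=lambda t: (-t[1], -t[2], t[0]))
    if k > len(ranked):
        logger.warning(
            "rank_keystones: k=%d exceeds %d taxa; returning all", k, len(ranked)
        )
        k = len(ranked)
    return [(taxon, pred) for taxon, pred, _ in ranked[:k]]
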