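"""Abundance tables: reading, writing, validation and rarefaction.

The central container is :class:`AbundanceStudy`, a taxon-by-sample count
matrix with a two-level sampling hierarchy attached to every sample: each
sample belongs to a *replicate* group, and each replicate group belongs to
an *ecosystem*. Downstream co-occurrence statistics treat replicates as
independent realizations of an ecosystem's community, so the hierarchy is
validated strictly here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceStudy",
    "RarefactionReport",
    "read_abundance",
    "write_abundance",
    "rarefy",
]


class ValidationError(ValueError):
    """Raised when a table violates the study invariants."""


@dataclass
class AbundanceStudy:
    """A taxon x sample count matrix with an ecosystem/replicate hierarchy.

    Parameters
    ----------
    counts
        Non-negative integer matrix, one row per taxon, one column per sample.
    taxon_ids
        Row labels (e.g. order or family names); unique, order preserved.
    sample_ids
        Column labels; unique, order preserved.
    sample_meta
        Mapping ``sample_id -> (ecosystem, replicate)``. Every sample must
        appear; a replicate label belongs to exactly one ecosystem.
    """

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    sample_meta: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self._validate()

    def _validate(self) -> None:
        n_taxa, n_samples = self.counts.shape
        if len(self.taxon_ids) != n_taxa or len(self.sample_ids) != n_samples:
            raise ValidationError(
                f"label/matrix shape mismatch: counts {self.counts.shape}, "
                f"{len(self.taxon_ids)} taxa, {len(self.sample_ids)} samples"
            )
        for name, labels in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(labels)[pd.Index(labels).duplicated()].unique().tolist()
            if dupes:
                raise ValidationError(f"duplicate {name} labels: {dupes}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.issubdtype(self.counts.dtype, np.floating) and np.all(
                np.mod(self.counts[np.isfinite(self.counts)], 1) == 0
            ):
                self.counts = self.counts.astype(np.int64)
            else:
                raise ValidationError("counts must be integral")
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at taxon {self.taxon_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        missing = [s for s in self.sample_ids if s not in self.sample_meta]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        # a replicate label may not straddle two ecosystems
        rep_eco: dict[str, str] = {}
        for sid in self.sample_ids:
            eco, rep = self.sample_meta[sid]
            if rep in rep_eco and rep_eco[rep] != eco:
                raise ValidationError(
                    f"replicate {rep!r} appears in ecosystems "
                    f"{rep_eco[rep]!r} and {eco!r}"
                )
            rep_eco[rep] = eco

    # -- hierarchy accessors -------------------------------------------------

    def ecosystems(self) -> list[str]:
        """Ecosystem labels in order of first appearance."""
        seen: dict[str, None] = {}
        for sid in self.sample_ids:
            seen.setdefault(self.sample_meta[sid][0], None)
        return list(seen)

    def replicates(self, ecosystem: str) -> list[str]:
        """Replicate labels of one ecosystem, in order of first appearance."""
        seen: dict[str, None] = {}
        for sid in self.sample_ids:
            eco, rep = self.sample_meta[sid]
            if eco == ecosystem:
                seen.setdefault(rep, None)
        return list(seen)

    def samples_of(self, ecosystem: str, replicate: str) -> list[str]:
        return [
            sid
            for sid in self.sample_ids
            if self.sample_meta[sid] == (ecosystem, replicate)
        ]

    def sample_indices(self, ecosystem: str, replicate: str) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array(
            [pos[s] for s in self.samples_of(ecosystem, replicate)], dtype=int
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)


@dataclass
class RarefactionReport:
    """Bookkeeping for one rarefaction pass."""

    depth: int
    kept_samples: list[str]
    dropped_samples: list[tuple[str, int]] = field(default_factory=list)
    seed: int = 0


def read_abundance(table_path, meta_path) -> AbundanceStudy:
    """Read a taxon-by-sample TSV plus a sample metadata TSV.

    The abundance table has a header row whose first cell is ``taxon`` and
    remaining cells are sample ids; the metadata table has columns
    ``sample_id``, ``ecosystem`` and ``replicate``.
    """
    try:
        tab = pd.read_csv(table_path, sep="\t", header=0, dtype={0: str})
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed abundance TSV {table_path}: {exc}") from exc
    if tab.columns[0] != "taxon":
        raise ValidationError(
            f"first header cell must be 'taxon', got {tab.columns[0]!r}"
        )
    taxa = tab.iloc[:, 0].astype(str).tolist()
    samples = [str(c) for c in tab.columns[1:]]
    values = tab.iloc[:, 1:]
    non_numeric = values.columns[
        ~values.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())
    ].tolist()
    if non_numeric:
        raise ValidationError(f"non-numeric counts in sample columns: {non_numeric}")
    counts = values.to_numpy()
    if not np.all(np.mod(counts, 1) == 0):
        r, c = np.argwhere(np.mod(counts, 1) != 0)[0]
        raise ValidationError(
            f"non-integer count {counts[r, c]} at taxon {taxa[r]!r}, "
            f"sample {samples[c]!r}"
        )
    counts = counts.astype(np.int64)

    try:
        meta = pd.read_csv(meta_path, sep="\t", header=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed metadata TSV {meta_path}: {exc}") from exc
    required = {"sample_id", "ecosystem", "replicate"}
    if not required.issubset(meta.columns):
        raise ValidationError(
            f"metadata must have columns {sorted(required)}, got {list(meta.columns)}"
        )
    sample_meta = {
        row.sample_id: (row.ecosystem, row.replicate) for row in meta.itertuples()
    }
    unknown = [s for s in samples if s not in sample_meta]
    if unknown:
        raise ValidationError(f"samples missing from metadata: {unknown}")
    sample_meta = {s: sample_meta[s] for s in samples}
    return AbundanceStudy(counts, taxa, samples, sample_meta)


def write_abundance(study: AbundanceStudy, table_path, meta_path) -> None:
    """Write a study back to the two-file TSV layout read_abundance expects."""
    frame = study.to_frame()
    frame.index.name = "taxon"
    frame.to_csv(table_path, sep="\t")
    meta = pd.DataFrame(
        [
            {
                "sample_id": s,
                "ecosystem": study.sample_meta[s][0],
                "replicate": study.sample_meta[s][1],
            }
            for s in study.sample_ids
        ]
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def rarefy(
    study: AbundanceStudy, depth: int, seed: int
) -> tuple[AbundanceStudy, RarefactionReport]:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Each retained column is a multivariate-hypergeometric draw from the
    sample's reads, so per-taxon counts never exceed the originals and the
    column sum is exactly ``depth``. Samples whose total is below ``depth``
    are dropped and reported. Dropping must not empty any replicate group.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = study.counts.sum(axis=0)
    keep_mask = totals >= depth
    dropped = [
        (s, int(t))
        for s, t, k in zip(study.sample_ids, totals, keep_mask)
        if not k
    ]
    kept = [s for s, k in zip(study.sample_ids, keep_mask) if k]
    kept_set = set(kept)
    for eco in study.ecosystems():
        for rep in study.replicates(eco):
            if not any(s in kept_set for s in study.samples_of(eco, rep)):
                raise ValueError(
                    f"rarefaction to depth {depth} drops every sample of "
                    f"replicate {rep!r} in ecosystem {eco!r}"
                )
    new_counts = np.zeros((len(study.taxon_ids), len(kept)), dtype=np.int64)
    col_positions = [i for i, k in enumerate(keep_mask) if k]
    for j, i in enumerate(col_positions):
        new_counts[:, j] = rng.multivariate_hypergeometric(study.counts[:, i], depth)
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d", len(dropped), depth)
    new_study = AbundanceStudy(
        new_counts,
        list(study.taxon_ids),
        kept,
        {s: study.sample_meta[s] for s in kept},
    )
    report = RarefactionReport(depth=depth, kept_samples=kept,
                               dropped_samples=dropped, seed=seed)
    return new_study, report
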