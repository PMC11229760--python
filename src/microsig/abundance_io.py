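"""Reading, validating and summarizing per-rank relative-abundance tables.

Tables are samples x taxa matrices of relative abundance in percent
(0-100) at a single taxonomic rank, paired with a binary group label per
sample (0 = non-metastatic "PC", 1 = metastatic "PC met").  The on-disk
format is plain TSV: one header row of taxon names, one row per sample,
plus a metadata TSV mapping sample_id -> group.  An optional reader for
the BIOM 2.1 HDF5 layout produces the same in-memory table.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "OTHERS_THRESHOLDS",
    "AbundanceTable",
    "CompositionSummary",
    "read_abundance_table",
    "read_metadata",
    "read_biom",
    "write_abundance_table",
    "aggregate_others",
    "alpha_diversity",
    "shannon_index",
    "chao1_index",
]

RANKS = ("phylum", "family", "genus", "species")

#: Default percent cutoffs below which taxa are folded into "Others".
OTHERS_THRESHOLDS = {"phylum": 1.0, "family": 1.0, "genus": 0.5, "species": 0.1}

_GROUP_ALIASES = {
    "0": 0, "1": 1, "pc": 0, "pc_met": 1, "pc met": 1, "pcmet": 1,
}

ROW_SUM_TOLERANCE = (99.0, 101.0)


@dataclass
class AbundanceTable:
    """Samples x taxa relative abundances (%) at one rank, with labels."""

    values: pd.DataFrame
    group: pd.Series
    rank: str = "genus"
    validation_log: list[str] = field(default_factory=list)
    validate: bool = True

    def __post_init__(self):
        if self.validate:
            self._validate()
        self.validate = True

    def _validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if v.columns.has_duplicates:
            raise ValueError("duplicate taxon identifiers within rank")
        arr = v.to_numpy(dtype=float)
        if np.any(arr < 0):
            raise ValueError("negative relative abundance")
        missing = v.index.difference(self.group.index)
        if len(missing):
            raise ValueError(f"samples without group label: {list(missing)}")
        self.group = self.group.loc[v.index].astype(int)
        if not set(np.unique(self.group)) <= {0, 1}:
            raise ValueError("group labels must be binary 0/1")
        sums = arr.sum(axis=1)
        lo, hi = ROW_SUM_TOLERANCE
        bad = (sums < lo) | (sums > hi)
        for sid, s in zip(v.index[bad], sums[bad]):
            self.validation_log.append(
                f"row sum {s:.3f} outside [{lo}, {hi}] for sample {sid!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def group_counts(self) -> dict[int, int]:
        return {int(k): int(v) for k, v in self.group.value_counts().items()}

    def validation_report(self) -> str:
        return json.dumps(
            {"n_samples": self.n_samples, "n_taxa": len(self.taxon_ids),
             "rank": self.rank, "group_counts": self.group_counts(),
             "warnings": self.validation_log},
            indent=2,
        )


@dataclass
class CompositionSummary:
    """Per-group mean relative abundance (%) after folding rare taxa."""

    group_means: pd.DataFrame  # taxa (incl. "Others") x group levels
    others_threshold: float
    folded_taxa: list[str]


def _coerce_group(s: pd.Series) -> pd.Series:
    def conv(x):
        key = str(x).strip().lower()
        if key in _GROUP_ALIASES:
            return _GROUP_ALIASES[key]
        raise ValueError(f"unrecognized group label {x!r}")
    return s.map(conv).astype(int)


def read_metadata(path: str | Path) -> pd.Series:
    """Read a metadata TSV with columns sample_id and group (0/1 or
    PC/PC_met); returns group labels indexed by sample id."""
    md = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in md.columns:
            raise ValueError(f"metadata is missing column {col!r}")
    if md["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    return _coerce_group(md.set_index("sample_id")["group"])


def read_abundance_table(
    path: str | Path,
    rank: str,
    metadata_path: str | Path,
) -> AbundanceTable:
    """Read a samples-in-rows TSV abundance table plus metadata.

    Rows are aligned to the metadata order by sample identifier; samples
    present in the metadata but absent from the table are reported in the
    validation log, samples without a group label are a hard error.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.index.name = None
    values.columns.name = None
    group = read_metadata(metadata_path)
    unlabeled = values.index.difference(group.index)
    if len(unlabeled):
        raise ValueError(f"samples without group label: {list(unlabeled)}")
    log: list[str] = []
    unmatched = group.index.difference(values.index)
    for sid in unmatched:
        log.append(f"metadata sample {sid!r} not present in abundance table")
    ordered = [sid for sid in group.index if sid in set(values.index)]
    table = AbundanceTable(values=values.loc[ordered], group=group, rank=rank)
    table.validation_log = log + table.validation_log
    return table


def write_abundance_table(table: AbundanceTable, path: str | Path,
                          metadata_path: str | Path | None = None) -> None:
    table.values.to_csv(path, sep="\t", index_label="sample_id")
    if metadata_path is not None:
        pd.DataFrame(
            {"sample_id": table.sample_ids, "group": table.group.to_numpy()}
        ).to_csv(metadata_path, sep="\t", index=False)


def read_biom(path: str | Path, rank: str, metadata_path: str | Path) -> AbundanceTable:
    """Read a BIOM 2.1 (HDF5) table into an AbundanceTable.

    Walks the standard layout: observation/ids, sample/ids and the CSC
    matrix under sample/matrix.  Values are interpreted as relative
    abundance in percent, matching the TSV reader.
    """
    import h5py

    with h5py.File(path, "r") as f:
        taxa = [t.decode() if isinstance(t, bytes) else str(t)
                for t in f["observation/ids"][:]]
        samples = [s.decode() if isinstance(s, bytes) else str(s)
                   for s in f["sample/ids"][:]]
        data = f["sample/matrix/data"][:]
        indices = f["sample/matrix/indices"][:]
        indptr = f["sample/matrix/indptr"][:]
    from scipy.sparse import csc_matrix

    mat = csc_matrix((data, indices, indptr), shape=(len(taxa), len(samples)))
    values = pd.DataFrame(mat.toarray().T, index=samples, columns=taxa)
    group = read_metadata(metadata_path)
    ordered = [sid for sid in group.index if sid in set(values.index)]
    return AbundanceTable(values=values.loc[ordered], group=group, rank=rank)


def aggregate_others(table: AbundanceTable, threshold: float | None = None) -> CompositionSummary:
    """Fold taxa with cohort-wide mean abundance below ``threshold`` percent
    into a single "Others" category; report per-group mean compositions.

    Default thresholds per rank: 1% (phylum, family), 0.5% (genus),
    0.1% (species)."""
    if table.values.empty:
        raise ValueError("empty abundance table")
    if threshold is None:
        threshold = OTHERS_THRESHOLDS.get(table.rank, 1.0)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    cohort_mean = table.values.mean(axis=0)
    folded = list(cohort_mean.index[cohort_mean < threshold])
    kept = [t for t in table.values.columns if t not in set(folded)]
    by_group = table.values.groupby(table.group).mean().T  # taxa x group
    summary = by_group.loc[kept]
    others = by_group.loc[folded].sum(axis=0)
    if folded:
        summary = pd.concat([summary, others.to_frame("Others").T])
    else:
        summary = pd.concat([summary, pd.DataFrame(0.0, index=["Others"],
                                                   columns=by_group.columns)])
    return CompositionSummary(group_means=summary, others_threshold=float(threshold),
                              folded_taxa=folded)


def shannon_index(composition: np.ndarray) -> float:
    """Shannon entropy in nats: -sum p_i ln p_i over nonzero proportions."""
    x = np.asarray(composition, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative entries")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero sample")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def chao1_index(counts: np.ndarray) -> float:
    """Chao1 richness: S_obs + F1^2/(2 F2), or S_obs + F1(F1-1)/2 when no
    doubletons are observed.  Defined for integer counts only."""
    x = np.asarray(counts)
    if np.any(x < 0):
        raise ValueError("negative entries")
    if not np.allclose(x, np.round(x)):
        raise ValueError("Chao1 requires integer counts")
    x = np.round(x).astype(int)
    s_obs = int((x > 0).sum())
    if s_obs == 0:
        raise ValueError("all-zero sample")
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def alpha_diversity(composition: np.ndarray) -> tuple[float, float | None]:
    """Per-sample (Shannon in nats, Chao1) pair.

    Chao1 is returned as None when the input is not integer counts
    (proportions carry no singleton/doubleton information)."""
    x = np.asarray(composition, dtype=float)
    sh = shannon_index(x)
    try:
        ch = chao1_index(x)
    except ValueError:
        ch = None
    return sh, ch
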