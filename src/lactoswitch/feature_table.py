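"""Samples x ASV count table with sample metadata and taxonomy.

The container mirrors what a 16S pipeline hands to downstream analysis:
an integer count matrix (samples in rows, amplicon sequence variants in
columns), per-sample metadata (group, day, mouse, cage) and per-feature
taxonomy (a rank-labelled lineage string plus a genus-assignment
confidence).  Everything is exchanged as tab-separated text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "read_feature_table", "write_feature_table"]

GROUPS = ("untreated", "model", "control", "test")
_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


class FeatureTable:
    """Validated samples x features count matrix with metadata and taxonomy.

    Parameters
    ----------
    counts : DataFrame, samples x features, non-negative integers.
    metadata : DataFrame indexed by sample id; must cover every sample.
        Expected columns: group, day, mouse_id, cage.
    taxonomy : optional DataFrame indexed by feature id with columns
        ``lineage`` (semicolon-separated, domain..species) and
        ``confidence`` (genus confidence in [0, 1]).
    """

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame,
                 taxonomy: pd.DataFrame | None = None):
        counts = counts.copy()
        if counts.index.has_duplicates or counts.columns.has_duplicates:
            raise ValueError("sample and feature ids must be unique")
        vals = counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(vals < 0) or np.any(vals != np.floor(vals)):
            raise ValueError("counts must be non-negative integers")
        counts = counts.astype(np.int64)

        missing = counts.index.difference(metadata.index)
        if len(missing):
            raise ValueError(f"metadata missing for samples: {list(missing)}")
        metadata = metadata.loc[counts.index].copy()

        if taxonomy is not None:
            missing_t = counts.columns.difference(taxonomy.index)
            if len(missing_t):
                raise ValueError(f"taxonomy missing for features: {list(missing_t)[:5]}")
            taxonomy = taxonomy.loc[counts.columns].copy()
            if "confidence" in taxonomy and (
                    (taxonomy["confidence"] < 0).any() or (taxonomy["confidence"] > 1).any()):
                raise ValueError("genus confidence must lie in [0, 1]")

        self.counts = counts
        self.metadata = metadata
        self.taxonomy = taxonomy

    # -- basic protocol ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions (no pseudocount)."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise ValueError(f"all-zero samples: {bad}")
        return self.counts.div(totals, axis=0)

    def lineage_rank(self, rank: str) -> pd.Series:
        """Extract one rank (e.g. 'class', 'genus') from the lineage strings."""
        if self.taxonomy is None:
            raise ValueError("no taxonomy attached")
        i = _RANKS.index(rank)
        return self.taxonomy["lineage"].map(
            lambda s: (s.split(";") + [""] * len(_RANKS))[i].strip())

    def select_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.counts.loc[list(sample_ids)], self.metadata,
                            self.taxonomy)

    def select_features(self, feature_ids) -> "FeatureTable":
        tax = self.taxonomy.loc[list(feature_ids)] if self.taxonomy is not None else None
        return FeatureTable(self.counts[list(feature_ids)], self.metadata, tax)

    def subset(self, pairs) -> "FeatureTable":
        """Samples whose (group, day) is in `pairs`."""
        pairs = {(g, int(d)) for g, d in pairs}
        keep = [s for s in self.sample_ids
                if (self.metadata.at[s, "group"], int(self.metadata.at[s, "day"])) in pairs]
        return self.select_samples(keep)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        same = self.counts.equals(other.counts) and self.metadata.equals(other.metadata)
        if self.taxonomy is None or other.taxonomy is None:
            return same and (self.taxonomy is None) == (other.taxonomy is None)
        return same and self.taxonomy.equals(other.taxonomy)

    # -- text IO -----------------------------------------------------------
    def write(self, outdir) -> dict[str, Path]:
        return write_feature_table(self, outdir)


def write_feature_table(table: FeatureTable, outdir) -> dict[str, Path]:
    """Write matrix/metadata/taxonomy as TSV files under `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "feature_table.tsv",
        "metadata": outdir / "sample_metadata.tsv",
    }
    table.counts.rename_axis("sample_id").to_csv(paths["matrix"], sep="\t")
    table.metadata.rename_axis("sample_id").to_csv(paths["metadata"], sep="\t")
    if table.taxonomy is not None:
        paths["taxonomy"] = outdir / "taxonomy.tsv"
        table.taxonomy.rename_axis("feature_id").to_csv(paths["taxonomy"], sep="\t")
    return paths


def read_feature_table(matrix_path, metadata_path, taxonomy_path=None) -> FeatureTable:
    """Read a FeatureTable from TSV files; matrix orientation auto-detected.

    The matrix may be samples x features or features x samples; orientation
    is resolved against the metadata sample ids.
    """
    counts = pd.read_csv(matrix_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0) if taxonomy_path else None

    samples = set(metadata.index.astype(str))
    rows_hit = sum(str(i) in samples for i in counts.index)
    cols_hit = sum(str(c) in samples for c in counts.columns)
    if cols_hit > rows_hit:
        counts = counts.T
        rows_hit = cols_hit
    if rows_hit < len(counts.index):
        offenders = [str(i) for i in counts.index if str(i) not in samples]
        raise ValueError(f"sample ids without metadata: {offenders[:5]}")
    return FeatureTable(counts, metadata, taxonomy)
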