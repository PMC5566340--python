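"""Transcript quantification: counts → RPKM → recA scaling → quantile normalization.

The chain mirrors a standard metatranscriptome workflow for a binned
community.  Raw per-gene mapped-hit counts are converted to RPKM (reads
per kilobase of gene length per million mapped reads, with the
per-sample total taken over the whole combined community, since reads
are mapped against one combined metagenome).  Each gene's RPKM is then
divided by the RPKM of its bin's single-copy recA marker, which cancels
between-sample shifts in taxon abundance so that the scaled values track
per-cell expression.  Quantile normalization finally forces identical
value distributions across sample conditions.  Genes are called
"actively expressed" when the normalized value reaches a floor
threshold (default 0.1, the same constant used as the fold-change
pseudocount).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CountTable",
    "ExpressionTable",
    "ExpressionError",
    "compute_rpkm",
    "normalize_recA",
    "quantile_normalize",
    "fold_change",
    "call_expressed",
    "read_counts",
    "write_counts",
    "lengths_from_gff",
    "DEFAULT_PSEUDOCOUNT",
    "DEFAULT_EXPRESSION_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_EXPRESSION_THRESHOLD = 0.1

_GENE_COLS = ["gene_id", "bin_id", "length_bp"]


class ExpressionError(ValueError):
    pass


@dataclass
class CountTable:
    """Raw mapped-hit counts per gene (rows) and sample condition (columns).

    ``genes`` is indexed by gene_id with columns bin_id and length_bp;
    ``counts`` shares the gene index, one integer column per sample.
    """

    genes: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def validate(self) -> None:
        if not self.genes.index.equals(self.counts.index):
            raise ExpressionError("genes and counts must share the gene index")
        if self.genes.index.has_duplicates:
            dups = self.genes.index[self.genes.index.duplicated()].tolist()
            raise ExpressionError(f"duplicate gene ids: {dups[:5]}")
        if (self.genes["length_bp"] <= 0).any():
            bad = self.genes.index[self.genes["length_bp"] <= 0].tolist()
            raise ExpressionError(f"non-positive gene lengths: {bad[:5]}")
        if (self.counts.values < 0).any():
            raise ExpressionError("negative counts")
        if not np.allclose(self.counts.values, np.round(self.counts.values)):
            raise ExpressionError("counts must be integral raw hit counts")


def compute_rpkm(table: CountTable) -> pd.DataFrame:
    """RPKM[g, s] = counts[g, s] × 10⁹ / (length_bp[g] × total_counts[s]).

    The denominator total is the per-sample sum over all genes of the
    combined community, not per-bin totals.
    """
    totals = table.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ExpressionError(
            f"sample(s) with zero total mapped reads: {list(zero.index)}"
        )
    lengths = table.genes["length_bp"].astype(float)
    return table.counts.astype(float).mul(1e9).div(totals, axis=1).div(lengths, axis=0)


def normalize_recA(
    rpkm: pd.DataFrame,
    bins: pd.Series,
    recA_map: dict[str, str],
) -> pd.DataFrame:
    """Divide each gene's RPKM by the RPKM of its bin's single-copy recA gene.

    This compensates for taxon-abundance variation between samples: after
    scaling, a bin's values are comparable across samples on a per-cell
    basis, and every recA gene maps to exactly 1.0.

    Parameters
    ----------
    bins
        Series mapping gene_id (index) → bin_id, aligned with ``rpkm``.
    recA_map
        bin_id → gene_id of that bin's designated recA marker.
    """
    missing_bins = sorted(set(bins.unique()) - set(recA_map))
    if missing_bins:
        raise ExpressionError(f"bins without a designated recA gene: {missing_bins}")
    out = pd.DataFrame(index=rpkm.index, columns=rpkm.columns, dtype=float)
    for bin_id, gene_ids in bins.groupby(bins).groups.items():
        recA_gene = recA_map[bin_id]
        if recA_gene not in rpkm.index:
            raise ExpressionError(
                f"recA gene {recA_gene!r} for bin {bin_id!r} missing from table"
            )
        denom = rpkm.loc[recA_gene]
        dead = denom[denom <= 0]
        if len(dead):
            raise ExpressionError(
                f"recA gene {recA_gene!r} of bin {bin_id!r} has zero RPKM in "
                f"sample(s) {list(dead.index)}"
            )
        out.loc[gene_ids] = rpkm.loc[gene_ids].div(denom, axis=1).values
        out.loc[recA_gene] = 1.0  # exact, by definition of self-normalization
    return out


def pick_recA(rpkm: pd.DataFrame, candidates: dict[str, list[str]]) -> dict[str, str]:
    """Resolve bins with several recA candidates to the highest-mean-RPKM copy."""
    out: dict[str, str] = {}
    for bin_id, genes in candidates.items():
        if not genes:
            raise ExpressionError(f"bin {bin_id!r} has no recA candidate")
        if len(genes) > 1:
            warnings.warn(
                f"bin {bin_id!r} has {len(genes)} recA candidates; "
                "using the one with highest mean RPKM",
                stacklevel=2,
            )
        out[bin_id] = max(genes, key=lambda g: float(rpkm.loc[g].mean()))
    return out


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force identical value distributions across columns.

    Rank each column; replace rank r with the mean of the r-th order
    statistics across columns.  Ties receive the mean of the order
    statistics their positions span, so tied entries stay tied.
    """
    if values.shape[1] < 2:
        raise ExpressionError("quantile normalization needs >= 2 samples")
    x = values.to_numpy(dtype=float)
    mean_sorted = np.sort(x, axis=0).mean(axis=1)
    prefix = np.concatenate([[0.0], np.cumsum(mean_sorted)])
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        lo = rankdata(x[:, j], method="min") - 1  # first position of the tie run
        hi = rankdata(x[:, j], method="max")      # one past the last position
        out[:, j] = (prefix[hi] - prefix[lo]) / (hi - lo)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def fold_change(
    values: pd.DataFrame,
    cond1: str,
    cond2: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Per-gene (values[cond1] + pc) / (values[cond2] + pc).

    The pseudocount (default 0.1) eliminates zero-division and damps fold
    changes of very low-abundance genes; with it, a gene absent from both
    conditions has fold change exactly 1.
    """
    for cond in (cond1, cond2):
        if cond not in values.columns:
            raise ExpressionError(f"unknown sample {cond!r}")
    if pseudocount < 0:
        raise ExpressionError("pseudocount must be >= 0")
    denom = values[cond2] + pseudocount
    if (denom == 0).any():
        bad = values.index[denom == 0].tolist()
        raise ExpressionError(
            f"zero denominator for genes {bad[:5]} with pseudocount {pseudocount}; "
            "use a positive pseudocount"
        )
    return (values[cond1] + pseudocount) / denom


def call_expressed(
    normalized: pd.DataFrame,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
) -> pd.DataFrame:
    """Boolean expressed calls: normalized value >= threshold (inclusive)."""
    if threshold < 0:
        raise ExpressionError("expression threshold must be >= 0")
    return normalized >= threshold


@dataclass
class ExpressionTable:
    """All stages of the normalization chain for one count table."""

    rpkm: pd.DataFrame
    rpkm_recA: pd.DataFrame
    normalized: pd.DataFrame
    expressed: pd.DataFrame
    recA_map: dict[str, str]
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD
    bins: pd.Series = field(default=None, repr=False)

    @classmethod
    def from_counts(
        cls,
        table: CountTable,
        recA_map: dict[str, str],
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
        quantile: bool = True,
    ) -> "ExpressionTable":
        """Run counts → RPKM → recA scaling → (optional) quantile normalization → calls."""
        rpkm = compute_rpkm(table)
        scaled = normalize_recA(rpkm, table.genes["bin_id"], recA_map)
        normalized = quantile_normalize(scaled) if quantile else scaled
        expressed = call_expressed(normalized, threshold)
        return cls(
            rpkm=rpkm,
            rpkm_recA=scaled,
            normalized=normalized,
            expressed=expressed,
            recA_map=dict(recA_map),
            pseudocount=pseudocount,
            threshold=threshold,
            bins=table.genes["bin_id"],
        )

    def expressed_genes(self, sample: str) -> set[str]:
        if sample not in self.expressed.columns:
            raise ExpressionError(f"unknown sample {sample!r}")
        col = self.expressed[sample]
        return set(col.index[col])

    def fold_change(self, cond1: str, cond2: str) -> pd.Series:
        """Fold change on recA-scaled values, as the descriptive ratio."""
        return fold_change(self.rpkm_recA, cond1, cond2, self.pseudocount)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_counts(path: str | Path) -> CountTable:
    """Read a counts TSV: gene_id, bin_id, length_bp, then one column per sample."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _GENE_COLS if c not in df.columns]
    if missing:
        raise ExpressionError(f"{path}: missing columns {missing}")
    df = df.set_index("gene_id")
    sample_cols = [c for c in df.columns if c not in ("bin_id", "length_bp")]
    if not sample_cols:
        raise ExpressionError(f"{path}: no sample count columns")
    return CountTable(
        genes=df[["bin_id", "length_bp"]],
        counts=df[sample_cols].astype(np.int64),
    )


def write_counts(table: CountTable, path: str | Path) -> None:
    out = pd.concat([table.genes, table.counts], axis=1)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def lengths_from_gff(path: str | Path, feature: str = "CDS") -> pd.Series:
    """Gene lengths (end − start + 1) from a GFF3 file, keyed by the ID attribute."""
    names = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names)
    df = df[df["type"] == feature]
    ids = df["attributes"].str.extract(r"ID=([^;]+)")[0]
    if ids.isna().any():
        raise ExpressionError(f"{path}: {feature} feature without an ID attribute")
    lengths = (df["end"].astype(int) - df["start"].astype(int) + 1).to_numpy()
    return pd.Series(lengths, index=ids.to_numpy(), name="length_bp")
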