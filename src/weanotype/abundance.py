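"""OTU-table preprocessing: sample QC, OTU filtering, rarefaction, rank
aggregation, and the relative-abundance transform.

The filtering chain mirrors standard 16S practice: samples under a read-depth
floor are dropped first; OTUs are then kept only if they have a known phylum,
are present (nonzero) in at least ``min_prevalence`` samples, and account for
strictly more than ``min_frac_total`` of the grand total of reads.
Rarefaction subsamples reads without replacement (multivariate
hypergeometric), one pass per sample, and is reproducible for a fixed seed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tables import UNKNOWN, CountTable, RelAbundanceTable, TaxonomyMap

log = logging.getLogger(__name__)

DEFAULT_MIN_READS = 5000
DEFAULT_MIN_PREVALENCE = 5
DEFAULT_MIN_FRAC_TOTAL = 1e-4
DEFAULT_RAREFACTION_DEPTH = 4831

AGG_RANKS = ("phylum", "class", "order", "family", "genus")


def qc_filter_samples(table: CountTable, min_reads: int = DEFAULT_MIN_READS) -> CountTable:
    """Drop samples with fewer than ``min_reads`` total reads."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    sums = table.sample_sums()
    keep = sums >= min_reads
    excluded = list(sums.index[~keep])
    if excluded:
        log.info("qc_filter_samples: excluded %d samples: %s", len(excluded), excluded)
    if not keep.any():
        raise ValueError(f"all {len(sums)} samples fall below min_reads={min_reads}")
    return CountTable(table.data.loc[keep])


def filter_otus(
    table: CountTable,
    taxonomy: TaxonomyMap,
    min_prevalence: int = DEFAULT_MIN_PREVALENCE,
    min_frac_total: float = DEFAULT_MIN_FRAC_TOTAL,
) -> CountTable:
    """Keep OTUs of known phylum, present in >= ``min_prevalence`` samples,
    with column share of the grand total strictly above ``min_frac_total``.

    Column order is preserved.  The operation is idempotent.
    """
    taxonomy.require(table.otu_ids)
    known = taxonomy.rank("phylum").reindex(table.otu_ids) != UNKNOWN
    prevalence = (table.data > 0).sum(axis=0) >= min_prevalence
    grand_total = table.data.to_numpy().sum()
    if grand_total == 0:
        raise ValueError("empty count table (grand total is zero)")
    frac = table.data.sum(axis=0) / grand_total > min_frac_total
    keep = known.to_numpy() & prevalence.to_numpy() & frac.to_numpy()
    log.info(
        "filter_otus: kept %d / %d OTUs (known phylum %d, prevalent %d, abundant %d)",
        int(keep.sum()), len(keep), int(known.sum()), int(prevalence.sum()), int(frac.sum()),
    )
    return CountTable(table.data.loc[:, keep])


def rarefy(table: CountTable, depth: int = DEFAULT_RAREFACTION_DEPTH, seed: int | None = None) -> CountTable:
    """Subsample each sample to exactly ``depth`` reads without replacement."""
    if seed is None:
        raise ValueError("rarefy requires an explicit seed")
    sums = table.sample_sums()
    short = sums < depth
    if short.any():
        raise ValueError(
            f"sample {sums.index[short][0]!r} has {int(sums[short].iloc[0])} reads "
            f"< rarefaction depth {depth}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i, row in enumerate(table.counts):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return CountTable(pd.DataFrame(out, index=table.data.index, columns=table.data.columns))


def _agg_frame(df: pd.DataFrame, taxonomy: TaxonomyMap, rank: str) -> pd.DataFrame:
    if rank not in AGG_RANKS:
        raise ValueError(f"rank must be one of {AGG_RANKS}, got {rank!r}")
    labels = taxonomy.rank(rank).reindex(df.columns)
    labels = labels.where(labels != UNKNOWN, f"unknown-{rank}")
    grouped = df.T.groupby(labels.to_numpy()).sum().T
    # stable, reader-friendly order: named ranks by descending total, sentinel last
    named = [c for c in grouped.columns if c != f"unknown-{rank}"]
    named.sort(key=lambda c: -grouped[c].sum())
    cols = named + [c for c in grouped.columns if c == f"unknown-{rank}"]
    return grouped[cols]


def aggregate(table: CountTable, taxonomy: TaxonomyMap, rank: str) -> CountTable:
    """Sum OTU counts into one column per named value of ``rank`` plus one
    ``unknown-<rank>`` column; the grand total is conserved."""
    taxonomy.require(table.otu_ids)
    return CountTable(_agg_frame(table.data, taxonomy, rank))


def aggregate_relative(rel: RelAbundanceTable, taxonomy: TaxonomyMap, rank: str) -> RelAbundanceTable:
    """Rank aggregation of an already-normalized table (row sums preserved)."""
    taxonomy.require(list(rel.data.columns))
    return RelAbundanceTable(_agg_frame(rel.data, taxonomy, rank))


def to_relative(table: CountTable) -> RelAbundanceTable:
    """Row-normalize counts; all-zero rows stay all-zero."""
    sums = table.data.sum(axis=1)
    safe = sums.replace(0, 1)
    return RelAbundanceTable(table.data.div(safe, axis=0))
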