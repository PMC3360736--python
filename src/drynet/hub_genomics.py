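"""Hub genes, chromosomal hub clusters and the QTL-overlap permutation test.

A gene's *intramodular connectivity* is its number of network edges to genes
of its own module; the top 20% most connected genes per module are the hub
genes. Summing intramodular connectivity in 1-Mb chromosome bins exposes
chromosomal regions packed with highly connected genes: runs of adjacent
bins whose summed connectivity exceeds 100, spanning more than 0.5 Mb of
sequence between the first and last contributing gene, are called *hub gene
clusters*. Whether these clusters coincide with drought-tolerance QTLs more
often than chance is tested by permutation: connectivity values are shuffled
over the fixed gene positions (only the pairing of value and position
matters for the null), clusters are re-called and the overlap recounted;
the p-value is the fraction of permutations whose overlap count strictly
exceeds the observed one.

All genomic coordinates are 0-based half-open; intervals that merely touch
do not overlap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mcl_modules import ModulePartition
from .network_build import CoexpressionNetwork

logger = logging.getLogger(__name__)

QTL_COLUMNS = ["chrom", "start", "end", "name"]


@dataclass
class GenomicTrack:
    """Per-gene genomic positions and connectivity, plus optional QTL intervals.

    genes
        DataFrame indexed by gene id with columns ``chrom``, ``start``,
        ``end`` (0-based half-open) and ``connectivity``.
    chrom_lengths
        Optional declared chromosome lengths; genes beyond a declared
        length are rejected by cluster detection.
    qtls
        Optional interval table (chrom, start, end, name).
    """

    genes: pd.DataFrame
    chrom_lengths: dict[str, int] | None = None
    qtls: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = {"chrom", "start", "end", "connectivity"} - set(self.genes.columns)
        if missing:
            raise ValueError(f"gene table lacks columns {sorted(missing)}")
        if (self.genes["start"] >= self.genes["end"]).any():
            bad = self.genes.index[self.genes["start"] >= self.genes["end"]]
            raise ValueError(f"start must be < end; offenders: {list(bad[:5])}")
        if (self.genes["connectivity"] < 0).any():
            raise ValueError("connectivity must be non-negative")

    def with_connectivity(self, connectivity: pd.Series) -> "GenomicTrack":
        genes = self.genes.copy()
        genes["connectivity"] = connectivity.reindex(genes.index).fillna(0.0)
        return GenomicTrack(genes=genes, chrom_lengths=self.chrom_lengths, qtls=self.qtls)

    def to_bed(self, path) -> None:
        bed = self.genes.reset_index()
        bed = bed[["chrom", "start", "end", bed.columns[0], "connectivity"]]
        bed.columns = ["chrom", "start", "end", "name", "score"]
        bed.to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def from_bed(cls, path, connectivity: pd.Series | None = None,
                 chrom_lengths: dict[str, int] | None = None) -> "GenomicTrack":
        bed = pd.read_csv(path, sep="\t", header=None,
                          names=["chrom", "start", "end", "name", "score"])
        genes = bed.set_index("name")
        genes["connectivity"] = (
            connectivity.reindex(genes.index).fillna(0.0)
            if connectivity is not None
            else genes.get("score", pd.Series(0.0, index=genes.index)).fillna(0.0)
        )
        return cls(genes=genes[["chrom", "start", "end", "connectivity"]],
                   chrom_lengths=chrom_lengths)


def read_qtl_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.assign(name=[f"qtl{i+1}" for i in range(len(df))])
    df.columns = QTL_COLUMNS
    return df


def write_qtl_bed(qtls: pd.DataFrame, path) -> None:
    qtls[QTL_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def intramodular_connectivity(
    net: CoexpressionNetwork, partition: ModulePartition
) -> pd.Series:
    """Count each gene's network edges to genes of its own module.

    Genes unassigned to any module (or assigned genes missing from the
    network) get connectivity 0.
    """
    module_of = partition.assignments
    counts = {g: 0 for g in partition.genes}
    for u, v in net.graph.edges():
        mu, mv = module_of.get(u), module_of.get(v)
        if mu is not None and mu == mv:
            counts[u] = counts.get(u, 0) + 1
            counts[v] = counts.get(v, 0) + 1
    for g in net.graph.nodes():
        counts.setdefault(g, 0)
    return pd.Series(counts, name="connectivity").sort_index()


def select_hubs(
    partition: ModulePartition,
    connectivity: pd.Series,
    fraction: float = 0.20,
) -> list[str]:
    """Top ``fraction`` most intramodularly connected genes of each module.

    Each module contributes ``ceil(fraction * size)`` genes; ties in
    connectivity are broken by gene id.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    hubs: list[str] = []
    for m in partition.module_ids:
        genes = partition.genes_in(m)
        n_hubs = math.ceil(fraction * len(genes))
        ranked = sorted(genes, key=lambda g: (-float(connectivity.get(g, 0)), g))
        hubs.extend(ranked[:n_hubs])
    return sorted(hubs)


# --- binned cluster calling ---------------------------------------------------
#
# The permutation test re-calls clusters hundreds of thousands of times, so the
# binning machinery is precomputed once (_BinnedTrack) and each call works on
# flat numpy arrays only.


class _BinnedTrack:
    """Gene positions mapped to global 1-Mb bin indices, chromosome-separated."""

    def __init__(self, track: GenomicTrack, bin_size: int):
        genes = track.genes
        self.gene_ids = genes.index.to_numpy()
        self.chroms = genes["chrom"].astype(str).to_numpy()
        self.starts = genes["start"].to_numpy(dtype=np.int64)
        self.ends = genes["end"].to_numpy(dtype=np.int64)
        self.k = genes["connectivity"].to_numpy(dtype=np.float64)

        if track.chrom_lengths:
            for c, L in track.chrom_lengths.items():
                beyond = (self.chroms == c) & (self.ends > L)
                if beyond.any():
                    raise ValueError(
                        f"genes beyond declared length of {c}: "
                        f"{list(self.gene_ids[beyond][:5])}"
                    )

        self.chrom_names, chrom_code = np.unique(self.chroms, return_inverse=True)
        local_bin = self.starts // bin_size
        # one empty guard bin between chromosomes so runs never cross them
        n_bins_per_chrom = np.zeros(len(self.chrom_names), dtype=np.int64)
        for c in range(len(self.chrom_names)):
            sel = chrom_code == c
            n_bins_per_chrom[c] = local_bin[sel].max() + 1 if sel.any() else 0
        offsets = np.concatenate([[0], np.cumsum(n_bins_per_chrom + 1)])
        self.bin_index = offsets[chrom_code] + local_bin
        self.n_bins = int(offsets[-1])
        self.bin_chrom_code = np.full(self.n_bins, -1, dtype=np.int64)
        self.bin_chrom_code[self.bin_index] = chrom_code

    def cluster_arrays(
        self, k: np.ndarray, score_threshold: float, min_span: float
    ) -> tuple[np.ndarray, ...]:
        """Call clusters for a connectivity vector; returns per-cluster arrays.

        Returns (chrom_code, region_start, region_end, span, score, bin_lo,
        bin_hi) for runs of adjacent bins with summed connectivity
        > score_threshold whose contributing genes (connectivity > 0) span
        > min_span between the first and last gene start. Region start/end
        extend from the first contributing gene's start to the last one's
        end.
        """
        pos = k > 0
        scores = np.bincount(self.bin_index[pos], weights=k[pos], minlength=self.n_bins)
        passing = np.flatnonzero(scores > score_threshold)
        if passing.size == 0:
            return tuple(np.empty(0, np.int64) for _ in range(7))

        # per-bin extrema over contributing genes (positive connectivity only)
        minstart = np.full(self.n_bins, np.iinfo(np.int64).max, dtype=np.int64)
        maxstart = np.full(self.n_bins, -1, dtype=np.int64)
        maxend = np.full(self.n_bins, -1, dtype=np.int64)
        np.minimum.at(minstart, self.bin_index[pos], self.starts[pos])
        np.maximum.at(maxstart, self.bin_index[pos], self.starts[pos])
        np.maximum.at(maxend, self.bin_index[pos], self.ends[pos])

        seg_starts = np.flatnonzero(np.diff(passing, prepend=passing[0] - 2) > 1)
        seg_ends = np.append(seg_starts[1:], passing.size) - 1
        run_min = np.minimum.reduceat(minstart[passing], seg_starts)
        run_maxstart = np.maximum.reduceat(maxstart[passing], seg_starts)
        run_maxend = np.maximum.reduceat(maxend[passing], seg_starts)
        run_score = np.add.reduceat(scores[passing], seg_starts)
        run_chrom = self.bin_chrom_code[passing[seg_starts]]

        span = run_maxstart - run_min
        keep = span > min_span
        return (run_chrom[keep], run_min[keep], run_maxend[keep], span[keep],
                run_score[keep], passing[seg_starts][keep], passing[seg_ends][keep])

    def member_genes(self, k: np.ndarray, bin_lo: int, bin_hi: int) -> list[str]:
        sel = (k > 0) & (self.bin_index >= bin_lo) & (self.bin_index <= bin_hi)
        return sorted(self.gene_ids[sel])


def detect_hub_clusters(
    track: GenomicTrack,
    bin_size: int = 1_000_000,
    score_threshold: float = 100.0,
    min_span: float = 500_000,
) -> pd.DataFrame:
    """Call chromosomal hub gene clusters from binned intramodular connectivity.

    Chromosomes are partitioned into consecutive ``bin_size`` intervals
    anchored at position 0; an interval's score is the summed connectivity
    of the genes starting in it. Runs of adjacent intervals with score
    strictly above ``score_threshold`` are merged; a run becomes a cluster
    when its contributing genes (connectivity > 0) span strictly more than
    ``min_span`` between the first and the last gene start. The reported
    region runs from the first contributing gene's start to the last one's
    end.

    Returns a DataFrame with columns ``chrom``, ``start``, ``end``,
    ``span``, ``score``, ``n_genes``, ``genes``.
    """
    if score_threshold <= 0:
        raise ValueError("score_threshold must be positive")
    bt = _BinnedTrack(track, bin_size)
    chrom_code, starts, ends, spans, scores, bin_lo, bin_hi = bt.cluster_arrays(
        bt.k, score_threshold, min_span
    )
    records = []
    for cc, s, e, sp, sc, b0, b1 in zip(
        chrom_code, starts, ends, spans, scores, bin_lo, bin_hi
    ):
        genes = bt.member_genes(bt.k, int(b0), int(b1))
        records.append(
            dict(chrom=str(bt.chrom_names[cc]), start=int(s), end=int(e),
                 span=int(sp), score=float(sc), n_genes=len(genes), genes=genes)
        )
    out = pd.DataFrame.from_records(
        records, columns=["chrom", "start", "end", "span", "score", "n_genes", "genes"]
    )
    return out.sort_values(["chrom", "start"]).reset_index(drop=True) if len(out) else out


def count_qtl_overlaps(clusters: pd.DataFrame, qtls: pd.DataFrame) -> int:
    """Number of hub clusters intersecting at least one QTL (half-open, >=1 bp)."""
    if len(clusters) == 0 or qtls is None or len(qtls) == 0:
        return 0
    c_chrom = set(clusters["chrom"].astype(str))
    q_chrom = set(qtls["chrom"].astype(str))
    if not c_chrom & q_chrom:
        raise ValueError(
            "chromosome naming mismatch between clusters and QTLs: "
            f"clusters use {sorted(c_chrom)[:3]}..., QTLs use {sorted(q_chrom)[:3]}..."
        )
    cs = clusters["start"].to_numpy()[:, None]
    ce = clusters["end"].to_numpy()[:, None]
    cc = clusters["chrom"].astype(str).to_numpy()[:, None]
    qs = qtls["start"].to_numpy()[None, :]
    qe = qtls["end"].to_numpy()[None, :]
    qc = qtls["chrom"].astype(str).to_numpy()[None, :]
    hit = (cc == qc) & (cs < qe) & (qs < ce)
    return int(hit.any(axis=1).sum())


@dataclass
class PermutationResult:
    actual: int
    null_counts: np.ndarray
    p_value: float
    n_perm: int
    plus_one: bool = False

    def format_p(self) -> str:
        if self.p_value == 0 and not self.plus_one:
            return f"< {1 / self.n_perm:g}"
        return f"{self.p_value:g}"


def permutation_test(
    track: GenomicTrack,
    qtls: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    bin_size: int = 1_000_000,
    score_threshold: float = 100.0,
    min_span: float = 500_000,
    plus_one: bool = False,
) -> PermutationResult:
    """Permutation test of hub-cluster / QTL overlap.

    Each permutation re-assigns the multiset of connectivity values to the
    multiset of gene positions at random (positions stay fixed; one label
    shuffle realizes both the connectivity and the position exchange, since
    only the pairing matters), re-calls hub clusters and recounts QTL
    overlaps. ``p = #(null count > actual) / n_perm`` — strictly greater,
    as in randomization tests reporting p = n/N; ``plus_one=True`` applies
    the conventional (n+1)/(N+1) correction instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    qtls = qtls if qtls is not None else track.qtls
    if qtls is None:
        raise ValueError("no QTL intervals supplied")
    rng = np.random.default_rng(seed)
    bt = _BinnedTrack(track, bin_size)

    chrom_to_code = {str(c): i for i, c in enumerate(bt.chrom_names)}
    unknown = [c for c in qtls["chrom"].astype(str) if c not in chrom_to_code]
    if len(unknown) == len(qtls) and len(qtls) > 0:
        raise ValueError(f"QTL chromosomes unknown to the gene track: {sorted(set(unknown))[:5]}")
    q = qtls[qtls["chrom"].astype(str).isin(chrom_to_code)]
    qc = np.array([chrom_to_code[c] for c in q["chrom"].astype(str)])
    qs = q["start"].to_numpy(dtype=np.int64)
    qe = q["end"].to_numpy(dtype=np.int64)

    def overlap_count(k: np.ndarray) -> int:
        cc, cs, ce, *_ = bt.cluster_arrays(k, score_threshold, min_span)
        if cc.size == 0 or qc.size == 0:
            return 0
        hit = (cc[:, None] == qc[None, :]) & (cs[:, None] < qe[None, :]) & (
            qs[None, :] < ce[:, None]
        )
        return int(hit.any(axis=1).sum())

    actual = overlap_count(bt.k)
    null_counts = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        null_counts[i] = overlap_count(rng.permutation(bt.k))
    exceed = int((null_counts > actual).sum())
    p = (exceed + 1) / (n_perm + 1) if plus_one else exceed / n_perm
    logger.info(
        "permutation test: actual=%d, null mean=%.2f sd=%.2f, p=%s",
        actual, null_counts.mean(), null_counts.std(), p,
    )
    return PermutationResult(
        actual=actual, null_counts=null_counts, p_value=float(p),
        n_perm=n_perm, plus_one=plus_one,
    )
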