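"""Position-weight-matrix comparison, clustering and annotation of cis-motifs.

Discovered promoter motifs (6-10 nt PWMs, e.g. from de novo discovery in the
1 kb upstream regions of co-expressed module genes) are compared pairwise by
the Pearson correlation of their probability matrices over the best ungapped
alignment, searching all relative offsets and both DNA strands. Motifs with
best correlation at or above a cutoff (0.65 by default) are clustered by
single linkage and each cluster is merged into one nonredundant PWM; merged
motifs are then annotated against reference PWMs (e.g. known plant
cis-regulatory elements such as the ABRE, consensus GCCACGTGKC), with
"unknown" assigned when no reference reaches the cutoff.

Motif files use a minimal MEME-like text format::

    MOTIF <id> [E=<evalue>]
    <p_A> <p_C> <p_G> <p_T>      # one line per motif position

Probability rows must sum to 1; count matrices (rows summing to a common
total > 1) are accepted and normalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
WIDTH_BOUNDS = (6, 10)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class MotifPWM:
    """A 4 x L position weight matrix (rows A, C, G, T; column-stochastic)."""

    id: str
    matrix: np.ndarray
    evalue: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError(f"{self.id}: PWM must be 4 x L")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"{self.id}: PWM columns must sum to 1 (got {sums})")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def reverse_complement(self) -> "MotifPWM":
        # complement = reverse base order (A<->T, C<->G), then reverse positions
        return MotifPWM(id=self.id, matrix=self.matrix[::-1, ::-1].copy(), evalue=self.evalue)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.matrix, axis=0))


def consensus_to_pwm(consensus: str, motif_id: str | None = None) -> MotifPWM:
    """Build a PWM from an IUPAC consensus; degenerate letters split probability equally."""
    cols = []
    for letter in consensus.upper():
        if letter not in IUPAC:
            raise ValueError(f"unknown IUPAC letter {letter!r}")
        allowed = IUPAC[letter]
        cols.append([1.0 / len(allowed) if b in allowed else 0.0 for b in BASES])
    return MotifPWM(id=motif_id or consensus, matrix=np.array(cols).T)


def is_mononucleotide_repeat(motif: MotifPWM) -> bool:
    """True when the consensus is a single repeated base (e.g. AAAAAA)."""
    return len(set(motif.consensus())) == 1


def filter_mononucleotide_repeats(
    motifs: Sequence[MotifPWM],
) -> tuple[list[MotifPWM], list[MotifPWM]]:
    """Input screen removing mono-nucleotide repeat motifs; returns (kept, removed)."""
    kept = [m for m in motifs if not is_mononucleotide_repeat(m)]
    removed = [m for m in motifs if is_mononucleotide_repeat(m)]
    if removed:
        logger.info("removed %d mono-nucleotide repeat motifs: %s",
                    len(removed), [m.id for m in removed])
    return kept, removed


def read_motifs(path, width_bounds: tuple[int, int] | None = WIDTH_BOUNDS) -> list[MotifPWM]:
    """Parse the minimal motif text format; validates stochastic columns and width.

    Count matrices are detected by rows summing to a common total above 1
    and converted to frequencies; any other deviation from row sum 1 is a
    format error reported with its line number. ``width_bounds=None``
    disables the width check (useful for reference motifs of any length).
    """
    motifs: list[MotifPWM] = []
    cur_id: str | None = None
    cur_ev: float | None = None
    rows: list[list[float]] = []
    first_line = 0

    def flush(line_no: int) -> None:
        nonlocal cur_id, cur_ev, rows
        if cur_id is None:
            return
        if not rows:
            raise ValueError(f"motif {cur_id!r} (line {first_line}): no matrix rows")
        arr = np.array(rows, dtype=float)  # positions x 4
        sums = arr.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            common = sums[0]
            if common > 1 + 1e-6 and np.allclose(sums, common, rtol=1e-6):
                arr = arr / sums[:, None]  # counts -> frequencies
            else:
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise ValueError(
                    f"motif {cur_id!r}: position {bad + 1} sums to {sums[bad]:g}, "
                    f"not 1 (line {first_line + 1 + bad})"
                )
        if width_bounds is not None and not (width_bounds[0] <= len(rows) <= width_bounds[1]):
            raise ValueError(
                f"motif {cur_id!r} (line {first_line}): width {len(rows)} outside "
                f"{list(width_bounds)}"
            )
        motifs.append(MotifPWM(id=cur_id, matrix=arr.T, evalue=cur_ev))
        cur_id, cur_ev, rows = None, None, []

    line_no = 0
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            if line.upper().startswith("MOTIF"):
                flush(line_no)
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"line {line_no}: MOTIF line lacks an id")
                cur_id = parts[1]
                cur_ev = None
                for tok in parts[2:]:
                    if tok.upper().startswith("E="):
                        cur_ev = float(tok[2:])
                first_line = line_no
            else:
                if cur_id is None:
                    raise ValueError(f"line {line_no}: matrix row before any MOTIF header")
                vals = [float(t) for t in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"line {line_no}: expected 4 values (A C G T), got {len(vals)}")
                rows.append(vals)
        flush(line_no)
    return motifs


def write_motifs(motifs: Iterable[MotifPWM], path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            header = f"MOTIF {m.id}"
            if m.evalue is not None:
                header += f" E={m.evalue:g}"
            fh.write(header + "\n")
            for col in m.matrix.T:
                fh.write(" ".join(f"{v:.10f}" for v in col) + "\n")
            fh.write("\n")


class PWMAlignment(NamedTuple):
    correlation: float
    offset: int  # position of b's first column within a's coordinates
    strand: str  # '+' = b as given, '-' = reverse complement of b


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:  # zero-variance overlap (e.g. both uniform): defined as 0
        return 0.0
    return float((xc @ yc) / denom)


def pwm_correlation(
    a: MotifPWM,
    b: MotifPWM,
    min_overlap: int = 6,
    search_strands: bool = True,
) -> PWMAlignment:
    """Best Pearson correlation between two PWMs over all ungapped alignments.

    All relative offsets with at least ``min_overlap`` overlapping columns
    are scanned, on the given strand of ``b`` and (with
    ``search_strands=True``) on its reverse complement; the correlation is
    computed across the flattened 4 x overlap probability values. Ties keep
    the first alignment encountered (forward strand, smallest offset), so
    the result is deterministic.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if min_overlap > min(a.width, b.width):
        raise ValueError(
            f"min_overlap={min_overlap} exceeds the narrower motif "
            f"(widths {a.width}, {b.width})"
        )
    candidates = [("+", b.matrix)]
    if search_strands:
        candidates.append(("-", b.reverse_complement().matrix))
    best = PWMAlignment(-np.inf, 0, "+")
    La, Lb = a.width, b.width
    for strand, bm in candidates:
        for offset in range(-(Lb - min_overlap), La - min_overlap + 1):
            lo, hi = max(0, offset), min(La, offset + Lb)
            if hi - lo < min_overlap:
                continue
            x = a.matrix[:, lo:hi].ravel()
            y = bm[:, lo - offset : hi - offset].ravel()
            r = _pearson(x, y)
            if r > best.correlation:
                best = PWMAlignment(r, offset, strand)
    return best


@dataclass
class MotifClusterSet:
    """Single-linkage motif clusters, their merged nonredundant PWMs, and annotations."""

    clusters: list[list[str]]
    merged: list[MotifPWM]
    correlations: pd.DataFrame | None = None
    annotation: pd.DataFrame | None = None


def cluster_and_merge(
    motifs: Sequence[MotifPWM],
    cutoff: float = 0.65,
    min_overlap: int = 6,
    search_strands: bool = True,
) -> MotifClusterSet:
    """Cluster similar motifs at ``r >= cutoff`` and merge each cluster.

    Clusters are the connected components of the pairwise
    best-correlation graph thresholded at the cutoff (single linkage).
    Each cluster is merged by aligning every member to the cluster's
    longest motif (ties: lexicographically smallest id) at its best
    offset/strand and averaging the probability columns of all covering
    members; merged columns are renormalized and the merged width equals
    the seed width.
    """
    if not motifs:
        raise ValueError("need at least one motif")
    ids = [m.id for m in motifs]
    if len(set(ids)) != len(ids):
        raise ValueError("motif ids must be unique")
    n = len(motifs)
    R = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = pwm_correlation(motifs[i], motifs[j], min_overlap, search_strands).correlation
            R[i, j] = R[j, i] = r

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if R[i, j] >= cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = [sorted(g) for _, g in sorted(groups.items())]

    merged: list[MotifPWM] = []
    for ci, members in enumerate(clusters, start=1):
        seed_idx = min(members, key=lambda i: (-motifs[i].width, motifs[i].id))
        seed = motifs[seed_idx]
        acc = np.zeros_like(seed.matrix)
        cover = np.zeros(seed.width)
        for i in members:
            if i == seed_idx:
                acc += seed.matrix
                cover += 1.0
                continue
            aln = pwm_correlation(seed, motifs[i], min_overlap, search_strands)
            mat = (
                motifs[i].matrix if aln.strand == "+"
                else motifs[i].reverse_complement().matrix
            )
            lo, hi = max(0, aln.offset), min(seed.width, aln.offset + motifs[i].width)
            acc[:, lo:hi] += mat[:, lo - aln.offset : hi - aln.offset]
            cover[lo:hi] += 1.0
        cover[cover == 0] = 1.0
        mat = acc / cover
        mat = mat / mat.sum(axis=0, keepdims=True)
        merged.append(MotifPWM(id=f"nr{ci}", matrix=mat))

    corr = pd.DataFrame(R, index=ids, columns=ids)
    return MotifClusterSet(
        clusters=[[ids[i] for i in members] for members in clusters],
        merged=merged,
        correlations=corr,
    )


def annotate_motifs(
    merged: MotifClusterSet | Sequence[MotifPWM],
    references: Sequence[MotifPWM],
    cutoff: float = 0.65,
    min_overlap: int = 6,
    search_strands: bool = True,
) -> pd.DataFrame:
    """Label each merged motif with its best-matching reference PWM.

    A motif whose best reference correlation falls below the cutoff is
    labeled ``unknown`` — the fate of motifs absent from the reference
    collections.
    """
    if not references:
        raise ValueError("references must be non-empty")
    pwms = merged.merged if isinstance(merged, MotifClusterSet) else list(merged)
    records = []
    for m in pwms:
        best_ref, best = None, PWMAlignment(-np.inf, 0, "+")
        for ref in references:
            aln = pwm_correlation(m, ref, min_overlap, search_strands)
            if aln.correlation > best.correlation:
                best_ref, best = ref, aln
        known = best.correlation >= cutoff
        records.append(
            dict(
                motif=m.id,
                reference=best_ref.id if best_ref is not None else None,
                correlation=best.correlation,
                annotation=best_ref.id if known else "unknown",
            )
        )
    out = pd.DataFrame.from_records(records)
    if isinstance(merged, MotifClusterSet):
        merged.annotation = out
    return out
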