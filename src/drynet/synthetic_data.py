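"""Synthetic multi-experiment expression compendia with planted network structure.

The generator emulates the statistical shape of a multi-set rice drought
microarray compendium: several experiment sets, each with control and stress
replicate groups on a log2 intensity scale; planted co-expression modules;
planted stress responses; gene positions on 12 chromosomes with optional
planted hub regions; QTL intervals that either track the hub regions
("planted") or are independent of gene placement ("null"); planted GO term
structure; and Dirichlet-column motif PWMs. Every downstream stage of the
analysis can therefore be tested against a known ground truth without any
array downloads.

Expression model
----------------
Biological replicates of one (set, condition) cell share their latent
biology, so all latent structure varies at the cell level while
measurement noise is per array::

    x[g, s] = mu_g + s_g * z[M(g), cell(s)] + b * h[cell(s)] + eps[g, s]

* ``z`` is the module's latent trajectory over the 2 x n_sets cells: its
  drought-response pattern (stress cells of the module's responding
  experiment sets carry the module sign — alternating up/down — times
  per-set magnitude multipliers, scaled by ``response_effect``) plus an
  orthogonal standardized condition-independent factor that tops the
  trajectory variance up to the budget implied by ``module_correlation``.
* ``s_g`` is the gene's loading on its module trajectory; per-gene
  correlation shares scatter around sqrt(module_correlation)
  (``module_correlation_spread``), so pairwise within-module |r|
  concentrates near the target while strong loaders are simultaneously
  strong responders — the module's hubs.
* A fraction of unassigned genes respond individually (gene-specific set
  subsets, signs and magnitudes): they pass the differential screen but
  correlate only moderately with one another, reproducing the
  responsive-but-unmodular gene pool that shapes the density curve.
* ``h`` is one global factor giving unassigned genes the target background
  correlation; ``eps`` is N(0, noise_sd^2) per gene and array.

Identical seeds give bit-identical output; the expression, genome, QTL, GO
and motif stages consume independent seed streams derived from the one
configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .deg_screen import CONTROL, STRESS, ExpressionSet
from .hub_genomics import GenomicTrack, QTL_COLUMNS
from .mcl_modules import ModulePartition
from .motif_compare import MotifPWM

# seed-stream labels, one per generator stage
_EXPR, _GENOME, _QTL, _GO, _MOTIF = 1, 2, 3, 4, 5

# response-pattern shape constants: a module responds in each set with
# probability 0.7 (at least 2 sets), with per-set and per-gene magnitude
# multipliers uniform on [0.6, 1.4]
_SET_INCLUSION_P = 0.7
_MIN_RESPONDING_SETS = 2
_MULTIPLIER_RANGE = (0.6, 1.4)

# null-model intramodular connectivity: weakly connected genes plus a hub
# tail reaching the usual maximum-link scale (~36). The mixture is chosen so
# binned scores cross the cluster threshold often enough that the null
# overlap count takes many distinct values — the permutation p-value is a
# discrete n/N statistic, and a coarse-grained count would distort its
# calibration.
_HUB_FRACTION = 0.35
_LOW_CONNECTIVITY_MEAN = 8.0
_HUB_CONNECTIVITY_RANGE = (12, 37)
_PLANTED_HUB_CONNECTIVITY = (25, 41)

_GENE_LENGTH_RANGE = (1_000, 5_001)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic compendium; defaults are the study conditions.

    module_correlation / background_correlation are target absolute Pearson
    correlations (within planted modules / among unassigned genes);
    response_effect is the mean |log2 fold change| scale of responsive
    modules; noise_sd the per-array residual sd on the log2 scale.
    planted_hub_regions is a list of (chrom, start, end) tuples; qtl_mode
    is "null" (QTLs independent of gene placement) or "planted" (every hub
    region covered by a QTL).
    """

    n_genes: int = 2000
    n_sets: int = 5
    replicates_per_condition: int = 3
    module_sizes: tuple[int, ...] = (150, 120, 100, 80, 60, 50, 45, 40, 35, 30)
    module_correlation: float = 0.9
    module_correlation_spread: float = 0.06
    background_correlation: float = 0.2
    background_responsive_fraction: float = 0.25
    response_effect: float = 1.5
    noise_sd: float = 0.4
    n_chromosomes: int = 12
    chromosome_length_bp: int = 30_000_000
    planted_hub_regions: tuple[tuple[str, int, int], ...] = ()
    hub_genes_per_region: int = 10
    n_qtls: int = 35
    qtl_length_range: tuple[int, int] = (2_000_000, 5_000_000)
    qtl_mode: str = "null"
    seed: int = 0

    def __post_init__(self) -> None:
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        self.qtl_length_range = tuple(int(v) for v in self.qtl_length_range)
        self.planted_hub_regions = tuple(
            (str(c), int(s), int(e)) for c, s, e in self.planted_hub_regions
        )
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) must not exceed n_genes")
        for name in ("module_correlation", "background_correlation"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.module_correlation <= self.background_correlation:
            raise ValueError(
                "module_correlation must exceed background_correlation; otherwise "
                "planted modules are undetectable by construction"
            )
        if self.qtl_mode not in {"null", "planted"}:
            raise ValueError(f"qtl_mode must be 'null' or 'planted', got {self.qtl_mode!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        chroms = self.chromosome_names
        for c, s, e in self.planted_hub_regions:
            if c not in chroms:
                raise ValueError(f"planted region on unknown chromosome {c!r}")
            if not (0 <= s < e <= self.chromosome_length_bp):
                raise ValueError(f"planted region ({c}, {s}, {e}) outside chromosome bounds")

    @property
    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chromosome_length_bp for c in self.chromosome_names}

    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["module_sizes"] = list(d["module_sizes"])
        d["planted_hub_regions"] = [list(r) for r in d["planted_hub_regions"]]
        d["qtl_length_range"] = list(d["qtl_length_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


def default_planted_regions(
    n_regions: int = 15,
    n_chromosomes: int = 12,
    region_bp: int = 2_000_000,
    first_start_bp: int = 10_000_000,
    spacing_bp: int = 8_000_000,
) -> tuple[tuple[str, int, int], ...]:
    """Evenly laid-out hub regions, Mb-aligned, cycling over the chromosomes."""
    regions = []
    for i in range(n_regions):
        chrom = f"chr{i % n_chromosomes + 1}"
        start = first_start_bp + (i // n_chromosomes) * spacing_bp
        regions.append((chrom, start, start + region_bp))
    return tuple(regions)


def planted_association_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study configuration for the hub-cluster/QTL association analysis.

    Planted hub regions across the genome, each guaranteed QTL coverage,
    with modules at the scale of the smaller published co-expression
    modules — the resulting network's summed connectivity per 1-Mb bin then
    sits well below the cluster threshold outside genuine hub
    concentrations, as in the real compendium, so the permutation test has
    a detectable association to find.
    """
    defaults = dict(
        seed=seed,
        qtl_mode="planted",
        planted_hub_regions=default_planted_regions(),
        module_sizes=(60, 50, 45, 40, 35, 30, 25, 25, 20, 20),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def planted_partition(config: SimulationConfig) -> ModulePartition:
    """Ground-truth module membership: the first genes fill the planted modules."""
    genes = config.gene_ids()
    assignments: dict[str, int] = {}
    i = 0
    for m, size in enumerate(config.module_sizes, start=1):
        for g in genes[i : i + size]:
            assignments[g] = m
        i += size
    return ModulePartition(assignments=assignments, unassigned=set(genes[i:]))


def _response_patterns(
    rng: np.random.Generator,
    n_items: int,
    n_sets: int,
    signs: Sequence[float] | None = None,
) -> np.ndarray:
    """Response patterns over the (set, condition) cells.

    Each item (module or individually responding gene) responds in a random
    subset of sets (at least 2) with per-set magnitude multipliers; signs
    alternate up/down when not supplied. Returns (n_items, n_sets, 2) where
    [..., 0] is the control cell (always 0) and [..., 1] the stress cell.
    """
    lo, hi = _MULTIPLIER_RANGE
    patterns = np.zeros((n_items, n_sets, 2))
    for m in range(n_items):
        responding = rng.random(n_sets) < _SET_INCLUSION_P
        if responding.sum() < _MIN_RESPONDING_SETS:
            forced = rng.choice(n_sets, size=_MIN_RESPONDING_SETS, replace=False)
            responding[:] = False
            responding[forced] = True
        sign = signs[m] if signs is not None else (1.0 if m % 2 == 0 else -1.0)
        mult = rng.uniform(lo, hi, size=n_sets)
        patterns[m, responding, 1] = sign * mult[responding]
    return patterns


def generate_expression_sets(config: SimulationConfig) -> list[ExpressionSet]:
    """Simulate one :class:`ExpressionSet` per experiment set.

    Genes of the same planted module share the module's response pattern
    and condition-independent factor, so their pairwise |r| over the
    concatenated profile concentrates near ``module_correlation``; stress
    cells of responding sets are shifted by about ``response_effect`` on
    the log2 scale with the module's sign. Identical seeds give
    bit-identical matrices.
    """
    rng = config._rng(_EXPR)
    genes = config.gene_ids()
    n_mod = len(config.module_sizes)
    module_of = np.zeros(config.n_genes, dtype=int)  # 0 = unassigned
    i = 0
    for m, size in enumerate(config.module_sizes, start=1):
        module_of[i : i + size] = m
        i += size

    mu = rng.uniform(5.0, 10.0, size=config.n_genes)
    # module response patterns over cells, scaled to the log2 effect size
    patterns = config.response_effect * _response_patterns(rng, n_mod, config.n_sets)

    # Each module follows one latent trajectory z over the (set, condition)
    # cells: its response pattern plus an orthogonal condition-independent
    # factor topping the trajectory variance up to the budget implied by the
    # correlation target, c = rho * sigma^2 / (1 - rho). Genes load on z
    # with per-gene shares t_g scattered around sqrt(module_correlation),
    # so pairwise within-module |r| ~ t_i * t_j concentrates on target
    # while strong loaders are simultaneously the strong responders (hubs).
    sigma2 = config.noise_sd**2
    t = np.clip(
        rng.normal(
            math.sqrt(config.module_correlation),
            config.module_correlation_spread,
            size=config.n_genes,
        ),
        0.05,
        0.995,
    )
    c_gene = t**2 * sigma2 / (1.0 - t**2)
    rho_mod = config.module_correlation
    c_bar = rho_mod * sigma2 / (1.0 - rho_mod)
    rho_bg = config.background_correlation
    b_loading = math.sqrt(rho_bg * sigma2 / (1.0 - rho_bg)) if rho_bg > 0 else 0.0

    n_cells = config.n_sets * 2
    pat_flat = patterns.reshape(n_mod, n_cells) if n_mod else np.zeros((0, n_cells))
    z_cells = np.zeros((n_mod, config.n_sets, 2))
    var_z = np.ones(n_mod)
    for m in range(n_mod):
        p = pat_flat[m]
        pc = p - p.mean()
        var_p = float(pc @ pc) / n_cells
        # factor draw residualized against the pattern and standardized, so
        # the realized trajectory variance is exact despite the few cells
        q = rng.standard_normal(n_cells)
        if pc @ pc > 0:
            q = q - (q @ pc) / (pc @ pc) * pc
        q = q - q.mean()
        q_sd = q.std()
        if q_sd > 0:
            q = q / q_sd
        gamma = math.sqrt(max(0.0, c_bar - var_p))
        z = p + gamma * q
        var_z[m] = var_p + gamma**2
        z_cells[m] = z.reshape(config.n_sets, 2)

    # per-gene loading on the module trajectory
    s_gene = np.zeros(config.n_genes)
    assigned_mask = module_of > 0
    s_gene[assigned_mask] = np.sqrt(
        c_gene[assigned_mask] / var_z[module_of[assigned_mask] - 1]
    )

    h_cells = rng.standard_normal((config.n_sets, 2))

    # a fraction of unassigned genes respond individually: gene-specific set
    # subsets, signs and magnitudes, so they pass the screen but correlate
    # only moderately with each other — the responsive-but-unmodular genes
    # whose progressive disconnection shapes the density curve's upturn
    bg_idx = np.flatnonzero(~assigned_mask)
    bg_responders = bg_idx[
        rng.random(bg_idx.size) < config.background_responsive_fraction
    ]
    bg_signs = np.where(rng.random(bg_responders.size) < 0.5, 1.0, -1.0)
    bg_patterns = config.response_effect * _response_patterns(
        rng, bg_responders.size, config.n_sets, signs=bg_signs
    )
    bg_u = rng.uniform(*_MULTIPLIER_RANGE, size=bg_responders.size)

    reps = config.replicates_per_condition
    esets = []
    for s in range(config.n_sets):
        set_id = f"set{s + 1}"
        cols, cond_idx = [], []
        for ci, cond in enumerate((CONTROL, STRESS)):
            for r in range(reps):
                cols.append(f"{set_id}.{cond[0]}{r + 1}")
                cond_idx.append(ci)
        cond_idx = np.array(cond_idx)

        x = np.tile(mu[:, None], (1, len(cols)))
        for ci in (0, 1):
            sel = cond_idx == ci
            cell = np.zeros(config.n_genes)
            midx = module_of[assigned_mask] - 1
            cell[assigned_mask] = s_gene[assigned_mask] * z_cells[midx, s, ci]
            cell[~assigned_mask] = b_loading * h_cells[s, ci]
            cell[bg_responders] += bg_u * bg_patterns[:, s, ci]
            x[:, sel] += cell[:, None]
        x += rng.normal(0.0, config.noise_sd, size=x.shape)

        design = pd.DataFrame(
            {
                "set": set_id,
                "condition": [CONTROL] * reps + [STRESS] * reps,
                "replicate": list(range(1, reps + 1)) * 2,
            },
            index=pd.Index(cols, name="sample"),
        )
        matrix = pd.DataFrame(x, index=pd.Index(genes, name="gene"), columns=cols)
        esets.append(ExpressionSet(matrix=matrix, design=design, set_id=set_id))
    return esets


def _designate_hub_members(
    config: SimulationConfig,
    partition: ModulePartition,
    connectivity: pd.Series | None,
) -> list[list[str]]:
    """Pick the genes to place inside each planted hub region.

    With a connectivity vector (the real network's intramodular
    connectivity), the globally most connected genes are dealt round-robin
    across regions, emulating hub genes clustering in chromosomes. Without
    one, module genes are taken round-robin across modules and get high
    synthetic connectivity draws instead.
    """
    n_regions = len(config.planted_hub_regions)
    n_needed = n_regions * config.hub_genes_per_region
    if n_regions == 0:
        return []
    if connectivity is not None:
        ranked = sorted(
            connectivity.index, key=lambda g: (-float(connectivity[g]), g)
        )[:n_needed]
    else:
        pools = [partition.genes_in(m) for m in partition.module_ids] or [
            sorted(partition.genes)
        ]
        ranked, depth = [], 0
        while len(ranked) < n_needed:
            added = False
            for pool in pools:
                if depth < len(pool):
                    ranked.append(pool[depth])
                    added = True
                    if len(ranked) == n_needed:
                        break
            depth += 1
            if not added:
                raise ValueError("not enough genes to populate planted hub regions")
    return [ranked[i::n_regions] for i in range(n_regions)]


def generate_genome_annotation(
    config: SimulationConfig,
    partition: ModulePartition,
    connectivity: pd.Series | None = None,
) -> GenomicTrack:
    """Place every gene on a chromosome; hub-cluster members go into planted regions.

    Genes designated hub-cluster members (see ``_designate_hub_members``)
    are positioned uniformly inside their planted region; all other genes
    are uniform over the genome. The returned track carries the supplied
    connectivity, or — when none is given — a synthetic null-model draw
    (mostly weakly connected genes with a 20% hub tail, and high values for
    designated members) so hub-level analyses can run without an expression
    pipeline.
    """
    rng = config._rng(_GENOME)
    genes = config.gene_ids()
    if not set(genes) >= partition.genes:
        raise ValueError("partition contains genes outside the simulated gene set")
    n = len(genes)
    gene_pos = pd.DataFrame(index=pd.Index(genes, name="gene"),
                            columns=["chrom", "start", "end"], dtype=object)

    lengths = rng.integers(*_GENE_LENGTH_RANGE, size=n)
    chrom = rng.integers(0, config.n_chromosomes, size=n)
    start = rng.integers(0, config.chromosome_length_bp - lengths.max(), size=n)
    gene_pos["chrom"] = [config.chromosome_names[c] for c in chrom]
    gene_pos["start"] = start
    gene_pos["end"] = start + lengths

    members = _designate_hub_members(config, partition, connectivity)
    designated: set[str] = set()
    for (chrom_name, lo, hi), region_genes in zip(config.planted_hub_regions, members):
        for g in region_genes:
            glen = int(rng.integers(*_GENE_LENGTH_RANGE))
            gs = int(rng.integers(lo, max(lo + 1, hi - glen)))
            gene_pos.loc[g, ["chrom", "start", "end"]] = (chrom_name, gs, gs + glen)
            designated.add(g)

    if connectivity is not None:
        k = connectivity.reindex(genes).fillna(0.0).to_numpy(dtype=float)
    else:
        hub_mask = rng.random(n) < _HUB_FRACTION
        k = np.where(
            hub_mask,
            rng.integers(*_HUB_CONNECTIVITY_RANGE, size=n),
            rng.poisson(_LOW_CONNECTIVITY_MEAN, size=n),
        ).astype(float)
        if designated:
            is_designated = np.array([g in designated for g in genes])
            k[is_designated] = rng.integers(
                *_PLANTED_HUB_CONNECTIVITY, size=int(is_designated.sum())
            )

    track_genes = gene_pos.astype({"start": np.int64, "end": np.int64})
    track_genes["connectivity"] = k
    return GenomicTrack(genes=track_genes, chrom_lengths=config.chrom_lengths)


def generate_qtls(config: SimulationConfig, track: GenomicTrack) -> pd.DataFrame:
    """QTL intervals; planted mode covers every hub region, null mode ignores genes."""
    rng = config._rng(_QTL)
    records: list[tuple[str, int, int, str]] = []
    L = config.chromosome_length_bp
    if config.qtl_mode == "planted":
        for c, lo, hi in config.planted_hub_regions:
            flank_l = int(rng.integers(100_000, 800_000))
            flank_r = int(rng.integers(100_000, 800_000))
            records.append((c, max(0, lo - flank_l), min(L, hi + flank_r), ""))
    n_random = config.n_qtls - len(records)
    for _ in range(max(0, n_random)):
        qlen = int(rng.integers(*config.qtl_length_range))
        c = config.chromosome_names[int(rng.integers(0, config.n_chromosomes))]
        s = int(rng.integers(0, max(1, L - qlen)))
        records.append((c, s, s + qlen, ""))
    qtls = pd.DataFrame(records, columns=QTL_COLUMNS)
    qtls["name"] = [f"qtl{i + 1}" for i in range(len(qtls))]
    return qtls


def planted_go_term(module_id: int) -> str:
    return f"GO:M{module_id:04d}"


def generate_go_annotation(
    config: SimulationConfig,
    partition: ModulePartition,
    coverage: float = 0.6,
    n_background_terms: int = 30,
    background_term_p: float = 0.05,
) -> pd.DataFrame:
    """Two-column gene -> GO-term table with one planted term per module.

    Each planted module gets a dedicated term covering ``coverage`` of its
    genes; background terms hit every gene independently, giving the
    hypergeometric enrichment a known right answer.
    """
    rng = config._rng(_GO)
    genes = config.gene_ids()
    records: list[tuple[str, str]] = []
    for m in partition.module_ids:
        members = partition.genes_in(m)
        n_cov = math.ceil(coverage * len(members))
        covered = rng.choice(members, size=n_cov, replace=False)
        records += [(g, planted_go_term(m)) for g in sorted(covered)]
    for t in range(n_background_terms):
        hit = rng.random(len(genes)) < background_term_p
        records += [(g, f"GO:BG{t:02d}") for g, h in zip(genes, hit) if h]
    return pd.DataFrame(records, columns=["gene", "term"])


def generate_motifs(
    config: SimulationConfig,
    n_motifs: int = 12,
    concentration: float = 0.5,
) -> list[MotifPWM]:
    """Random Dirichlet-column PWMs of width 6-10 for motif-pipeline tests."""
    rng = config._rng(_MOTIF)
    motifs = []
    for i in range(n_motifs):
        width = int(rng.integers(6, 11))
        cols = rng.dirichlet(np.full(4, concentration), size=width).T
        motifs.append(MotifPWM(id=f"m{i + 1}", matrix=cols))
    return motifs


# --- plain-text export of a full synthetic input bundle ----------------------


def write_gene_bed(track: GenomicTrack, path) -> None:
    track.to_bed(path)


def write_inputs(
    config: SimulationConfig,
    outdir,
    esets: Sequence[ExpressionSet],
    track: GenomicTrack | None = None,
    qtls: pd.DataFrame | None = None,
    go: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the synthetic inputs in their on-disk formats; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    design_all = pd.concat([e.design for e in esets])
    expr_all = pd.concat([e.matrix for e in esets], axis=1)
    paths["expression"] = outdir / "expression.tsv"
    paths["design"] = outdir / "design.tsv"
    expr_all.to_csv(paths["expression"], sep="\t", index_label="gene")
    design_all.to_csv(paths["design"], sep="\t", index_label="sample")
    if track is not None:
        paths["genes_bed"] = outdir / "genes.bed"
        track.to_bed(paths["genes_bed"])
    if qtls is not None:
        paths["qtl_bed"] = outdir / "qtls.bed"
        qtls[QTL_COLUMNS].to_csv(paths["qtl_bed"], sep="\t", index=False, header=False)
    if go is not None:
        paths["go_tsv"] = outdir / "gene2go.tsv"
        go.to_csv(paths["go_tsv"], sep="\t", index=False)
    paths["config"] = outdir / "sim_config.yaml"
    config.to_yaml(paths["config"])
    return paths
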