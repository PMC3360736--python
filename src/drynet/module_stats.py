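"""Module-level statistics: drought-response significance, tissue profiles, GO enrichment.

The response statistic of a module in a dataset is the mean of the absolute
log2-fold expression changes of its genes; significance of the difference
from the whole-network average is assessed by a t-test, and a module is
flagged (starred) only when its mean exceeds the network average at
p < 0.001 — direction matters, so a module significantly *below* the
average is not flagged. Functional coherence is tested per module by the
upper-tail hypergeometric distribution with a Bonferroni correction over
the terms tested within the module.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .mcl_modules import ModulePartition

logger = logging.getLogger(__name__)


def _one_sample_t(values: np.ndarray, popmean: float) -> tuple[float, float]:
    # zero-variance samples: t = 0 / p = 1 when they sit on the reference,
    # otherwise infinitely far from it
    if values.std(ddof=1) == 0:
        if np.isclose(values.mean(), popmean):
            return 0.0, 1.0
        return math.copysign(math.inf, values.mean() - popmean), 0.0
    t, p = stats.ttest_1samp(values, popmean)
    return float(t), float(p)


def module_response_significance(
    partition: ModulePartition,
    fold_changes: pd.Series,
    star_alpha: float = 0.001,
    two_sample: bool = False,
) -> pd.DataFrame:
    """Score each module's drought response against the network average.

    Parameters
    ----------
    partition
        Gene -> module assignment (unassigned genes contribute to the
        network average and get their own summary row).
    fold_changes
        Per-gene log2 fold change for one dataset; absolute values are the
        response statistic.
    star_alpha
        Significance level of the star flag (mean above network average AND
        p below this level).
    two_sample
        By default the module's |log2fc| values are tested against the
        network average as a fixed reference (one-sample t-test, two-sided),
        matching a single network-wide average per dataset. ``True``
        switches to a Welch two-sample test of module vs all other genes.

    Returns a DataFrame indexed by module id (plus ``unassigned`` and
    ``network`` summary rows carrying means only) with columns
    ``mean_abs_log2fc``, ``n``, ``t``, ``p``, ``starred``.
    """
    abs_fc = fold_changes.abs().dropna()
    universe = [g for g in partition.genes if g in abs_fc.index]
    if not universe:
        raise ValueError("no fold changes available for partition genes")
    network_vals = abs_fc.loc[universe].to_numpy()
    network_mean = float(network_vals.mean())

    rows: dict[object, dict] = {}
    for m in partition.module_ids:
        genes = [g for g in partition.genes_in(m) if g in abs_fc.index]
        vals = abs_fc.loc[genes].to_numpy()
        if len(vals) == 0:
            logger.warning("module %s absent from dataset; p undefined", m)
            rows[m] = dict(mean_abs_log2fc=np.nan, n=0, t=np.nan, p=np.nan, starred=False)
            continue
        mean = float(vals.mean())
        if len(vals) < 2:
            logger.warning("module %s has <2 genes with fold changes; p undefined", m)
            t = p = np.nan
        elif two_sample:
            rest = abs_fc.loc[[g for g in universe if partition.assignments.get(g) != m]]
            t, p = stats.ttest_ind(vals, rest.to_numpy(), equal_var=False)
            t, p = float(t), float(p)
        else:
            t, p = _one_sample_t(vals, network_mean)
        starred = bool(mean > network_mean and not np.isnan(p) and p < star_alpha)
        rows[m] = dict(mean_abs_log2fc=mean, n=len(vals), t=t, p=p, starred=starred)

    un = [g for g in partition.unassigned if g in abs_fc.index]
    rows["unassigned"] = dict(
        mean_abs_log2fc=float(abs_fc.loc[un].mean()) if un else np.nan,
        n=len(un), t=np.nan, p=np.nan, starred=False,
    )
    rows["network"] = dict(
        mean_abs_log2fc=network_mean, n=len(universe), t=np.nan, p=np.nan, starred=False
    )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "module"
    return out


def tissue_profile(partition: ModulePartition, tissue_expr: pd.DataFrame) -> pd.DataFrame:
    """Average each module's genes over a gene x tissue mean-expression table.

    Entry (m, t) is the mean over module-m genes of their tissue-t average
    expression; modules with no gene in the table yield NaN entries and a
    warning.
    """
    if not set(tissue_expr.index) & partition.genes:
        raise ValueError("tissue table covers no partition gene")
    rows = {}
    for m in partition.module_ids:
        genes = [g for g in partition.genes_in(m) if g in tissue_expr.index]
        if not genes:
            logger.warning("module %s has no gene in the tissue table", m)
            rows[m] = pd.Series(np.nan, index=tissue_expr.columns)
        else:
            rows[m] = tissue_expr.loc[genes].mean(axis=0)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "module"
    return out


def go_enrichment(
    partition: ModulePartition,
    annotation: pd.DataFrame | Mapping[str, Iterable[str]],
    background: Iterable[str] | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric GO-term enrichment per module, Bonferroni-corrected.

    For a term with K carriers among the N background genes, a module with
    n background genes of which k carry the term scores
    ``p = P(X >= k), X ~ Hypergeom(N, K, n)``. The Bonferroni factor is the
    number of terms tested within that module (terms with k >= 1); a term
    is enriched when the adjusted p falls below ``alpha``.

    ``annotation`` is a two-column DataFrame (gene, term) or a mapping
    gene -> terms. ``background`` defaults to all annotated genes; genes
    annotated but outside the background are skipped with a warning.
    """
    if isinstance(annotation, pd.DataFrame):
        pairs = annotation.iloc[:, :2].itertuples(index=False)
        gene_terms: dict[str, set[str]] = {}
        for g, t in pairs:
            gene_terms.setdefault(str(g), set()).add(str(t))
    else:
        gene_terms = {g: set(ts) for g, ts in annotation.items()}

    background = set(background) if background is not None else set(gene_terms)
    outside = set(gene_terms) - background
    if outside:
        logger.warning(
            "%d annotated genes outside the background are ignored", len(outside)
        )
    N = len(background)
    term_bg: dict[str, int] = {}
    for g in background:
        for t in gene_terms.get(g, ()):
            term_bg[t] = term_bg.get(t, 0) + 1

    records = []
    for m in partition.module_ids:
        genes = [g for g in partition.genes_in(m) if g in background]
        n = len(genes)
        counts: dict[str, int] = {}
        for g in genes:
            for t in gene_terms.get(g, ()):
                counts[t] = counts.get(t, 0) + 1
        n_tested = len(counts)
        for term, k in sorted(counts.items()):
            K = term_bg[term]
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            p_adj = min(1.0, p * n_tested)
            records.append(
                dict(module=m, term=term, k=k, n=n, K=K, N=N,
                     p=p, p_adj=p_adj, enriched=bool(p_adj < alpha))
            )
    return pd.DataFrame.from_records(
        records, columns=["module", "term", "k", "n", "K", "N", "p", "p_adj", "enriched"]
    )
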