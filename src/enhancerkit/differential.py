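"""Fold-change differential calls for eRNA windows and gene bodies.

The primary decision rule is fold-change plus an expression floor, which is
what the downstream enhancer definitions consume. An optional exact test
(binomial conditioning of two Poisson counts on their sum) with
Benjamini-Hochberg adjustment is available for gene-body calls.

Boundary semantics differ deliberately between the two layers: eRNA calls
use a strict fold-change cut (fc > 1.5), gene calls an inclusive one
(fc >= 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import TssRecord
from .tags import TagDirectory, count_window, quantify_gene_body

__all__ = ["DiffResult", "differential_ernas", "differential_genes", "bh_adjust"]


@dataclass
class DiffResult:
    unit: str
    count_a: float
    count_b: float
    fc: float
    call: str  # up | down | unchanged | low_expressed
    pvalue: float | None = None
    padj: float | None = None


def _check_same_genome(dir_a: TagDirectory, dir_b: TagDirectory) -> None:
    if dict(dir_a.chrom_sizes) != dict(dir_b.chrom_sizes):
        raise ValueError("directories have mismatched chromosome namespaces")


def _fc_call(
    count_a: float,
    count_b: float,
    fc: float,
    fc_cut: float,
    floor: float,
    inclusive: bool,
) -> str:
    if max(count_a, count_b) < floor:
        return "low_expressed"
    up = fc >= fc_cut if inclusive else fc > fc_cut
    down = fc <= 1.0 / fc_cut if inclusive else fc < 1.0 / fc_cut
    if up and count_b >= floor:
        return "up"
    if down and count_a >= floor:
        return "down"
    return "unchanged"


def differential_ernas(
    dir_a: TagDirectory,
    dir_b: TagDirectory,
    centers: Sequence[tuple[str, int]],
    halfwidth: int = 1000,
    fc_cut: float = 1.5,
    floor: float = 10.0,
    pc: float = 1.0,
) -> list[DiffResult]:
    """Differential eRNA calls over +/- ``halfwidth`` windows (both strands
    pooled); fc = (b + pc)/(a + pc), "up" requires fc > fc_cut (strict)."""
    _check_same_genome(dir_a, dir_b)
    out = []
    for chrom, center in centers:
        a = count_window(dir_a, chrom, center, halfwidth)
        b = count_window(dir_b, chrom, center, halfwidth)
        fc = (b + pc) / (a + pc)
        out.append(
            DiffResult(
                unit=f"{chrom}:{center}",
                count_a=a,
                count_b=b,
                fc=fc,
                call=_fc_call(a, b, fc, fc_cut, floor, inclusive=False),
            )
        )
    return out


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def exact_binomial_pvalue(k_a: int, k_b: int, total_a: int, total_b: int) -> float:
    """Two-sided exact test of two Poisson counts, conditioning on the sum:
    k_b ~ Binomial(k_a + k_b, total_b / (total_a + total_b)) under the null."""
    n = k_a + k_b
    if n == 0:
        return 1.0
    p = total_b / (total_a + total_b)
    return stats.binomtest(k_b, n, p, alternative="two-sided").pvalue


def differential_genes(
    dir_a: TagDirectory,
    dir_b: TagDirectory,
    genes: Sequence[TssRecord],
    fc_cut: float = 1.5,
    density_floor: float = 10.0,
    test: str = "none",
    pc: float = 1.0,
    body_cap: int = 13_000,
    promoter_exclusion: int = 500,
) -> list[DiffResult]:
    """Gene-body differential calls (sense strand, first ``body_cap`` bp,
    promoter-proximal region excluded).

    ``density_floor`` is in normalized tags per kb of quantified body; "up"
    requires fc >= fc_cut (inclusive). With ``test="poisson_exact"`` a
    two-sided conditional binomial test on the raw capped counts is computed
    and BH-adjusted across the result set.
    """
    if test not in ("none", "poisson_exact"):
        raise ValueError(f"unknown test {test!r}")
    _check_same_genome(dir_a, dir_b)
    if not genes:
        return []
    results: list[DiffResult] = []
    raw_pairs: list[tuple[int, int]] = []
    for gene in genes:
        a = quantify_gene_body(dir_a, gene, body_cap, promoter_exclusion)
        b = quantify_gene_body(dir_b, gene, body_cap, promoter_exclusion)
        span_kb = (min(body_cap, gene.length) - promoter_exclusion) / 1000.0
        dens_a, dens_b = a / span_kb, b / span_kb
        fc = (b + pc) / (a + pc)
        if max(dens_a, dens_b) < density_floor:
            call = "low_expressed"
        else:
            call = _fc_call(a, b, fc, fc_cut, floor=0.0, inclusive=True)
        results.append(DiffResult(unit=gene.gene, count_a=a, count_b=b, fc=fc, call=call))
        if test == "poisson_exact":
            ka = int(quantify_gene_body(dir_a, gene, body_cap, promoter_exclusion, normalized=False))
            kb = int(quantify_gene_body(dir_b, gene, body_cap, promoter_exclusion, normalized=False))
            raw_pairs.append((ka, kb))
    if test == "poisson_exact":
        pvals = [
            exact_binomial_pvalue(ka, kb, dir_a.capped_total, dir_b.capped_total)
            for ka, kb in raw_pairs
        ]
        padj = bh_adjust(pvals)
        for r, p, q in zip(results, pvals, padj):
            r.pvalue = float(p)
            r.padj = float(q)
    return results
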