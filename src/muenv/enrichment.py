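"""Preranked gene-set enrichment on the moderated-t-ranked gene list.

The enrichment score (ES) is the weighted Kolmogorov-Smirnov-style running
sum: walking down the ranked list, genes in the set increment the sum by
|stat|^weight / N_R (N_R the sum of |stat|^weight over set members), genes
outside decrement by 1/(N - N_hits); ES is the running-sum value of maximal
absolute deviation, signed.  Significance uses gene-set permutation: null ES
values from random same-size sets drawn from the ranked universe, NES =
ES / mean(|null ES| of matching sign), a one-sided permutation p on the
matching sign, and the positive/negative pooled FDR of the GSEA method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneSetCollection

logger = logging.getLogger("muenv")

__all__ = ["EnrichmentResult", "enrichment_score", "gsea_preranked"]


@dataclass
class EnrichmentResult:
    """Per-set enrichment table (es, nes, p_perm, fdr_q, size_used, direction)."""

    table: pd.DataFrame  # index set_name

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["fdr_q"] < fdr]

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index_label="set_name",
                          float_format="%.10g")


def _check_ranked(ranked: list[tuple[str, float]]) -> None:
    stats_ = [s for _, s in ranked]
    if any(a < b for a, b in zip(stats_, stats_[1:])):
        raise ValueError("ranked list must be sorted by statistic, descending")


def enrichment_score(
    ranked: list[tuple[str, float]],
    geneset: set[str],
    weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """ES and full running sum of one gene set on a ranked list."""
    _check_ranked(ranked)
    genes = [g for g, _ in ranked]
    stats_ = np.array([s for _, s in ranked], dtype=float)
    hit = np.fromiter((g in geneset for g in genes), dtype=bool, count=len(genes))
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if n_hits == len(genes):
        raise ValueError("gene set covers the whole ranked list")
    w = np.abs(stats_) ** weight
    n_r = w[hit].sum()
    if n_r == 0:
        raise ValueError("all hit statistics are zero; ES undefined")
    steps = np.where(hit, w / n_r, -1.0 / (len(genes) - n_hits))
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _null_es(
    stats_: np.ndarray,
    set_size: int,
    n_perm: int,
    weight: float,
    rng: np.random.Generator,
    chunk: int = 250,
) -> np.ndarray:
    """Null ES distribution from random same-size sets (vectorized, chunked)."""
    n = len(stats_)
    w = np.abs(stats_) ** weight
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        hit = np.zeros((m, n), dtype=bool)
        for i in range(m):
            hit[i, rng.choice(n, size=set_size, replace=False)] = True
        wh = np.where(hit, w[None, :], 0.0)
        n_r = wh.sum(axis=1, keepdims=True)
        n_r[n_r == 0] = 1.0  # degenerate all-zero-stat draws
        steps = np.where(hit, wh / n_r, -1.0 / (n - set_size))
        running = np.cumsum(steps, axis=1)
        idx = np.argmax(np.abs(running), axis=1)
        out[done : done + m] = running[np.arange(m), idx]
        done += m
    return out


def gsea_preranked(
    ranked: list[tuple[str, float]],
    collection: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> EnrichmentResult:
    """Gene-set-permutation GSEA over a collection; deterministic given seed."""
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    _check_ranked(ranked)
    rng = np.random.default_rng(seed)
    genes = [g for g, _ in ranked]
    universe = set(genes)
    stats_ = np.array([s for _, s in ranked], dtype=float)

    # observed ES per set, skipping non-overlapping sets
    observed: dict[str, tuple[float, int]] = {}
    for name, members in sorted(collection, key=lambda kv: kv[0]):
        used = len(members & universe)
        if used == 0 or used == len(genes):
            logger.warning("gene set %s skipped (overlap %d)", name, used)
            continue
        es, _ = enrichment_score(ranked, members, weight)
        observed[name] = (es, used)

    # shared null per distinct set size
    sizes = sorted({used for _, used in observed.values()})
    null_by_size = {
        k: _null_es(stats_, k, n_perm, weight, rng) for k in sizes
    }

    rows = []
    null_nes_all = []
    for name, (es, used) in observed.items():
        null = null_by_size[used]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        mean_abs = np.abs(same).mean() if len(same) else np.nan
        nes = es / mean_abs if mean_abs and np.isfinite(mean_abs) else np.nan
        if len(same):
            p = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + len(same))
        else:
            p = 1.0
        pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            null_nes = np.where(null >= 0, null / pos_mean, null / neg_mean)
        null_nes_all.append(null_nes[np.isfinite(null_nes)])
        rows.append((name, es, nes, p, used, "positive" if es >= 0 else "negative"))

    table = pd.DataFrame(
        rows, columns=["set_name", "es", "nes", "p_perm", "size_used", "direction"]
    ).set_index("set_name")

    # FDR by the pooled positive/negative NES scheme
    pooled = np.concatenate(null_nes_all) if null_nes_all else np.array([])
    obs_nes = table["nes"].to_numpy()
    fdr = np.full(len(table), np.nan)
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes):
            fdr[i] = 1.0
            continue
        if nes >= 0:
            null_frac_den = (pooled >= 0).sum()
            null_frac = (pooled >= nes).sum() / null_frac_den if null_frac_den else 1.0
            obs_den = (obs_nes >= 0).sum()
            obs_frac = (obs_nes >= nes).sum() / obs_den if obs_den else 1.0
        else:
            null_frac_den = (pooled < 0).sum()
            null_frac = (pooled <= nes).sum() / null_frac_den if null_frac_den else 1.0
            obs_den = (obs_nes < 0).sum()
            obs_frac = (obs_nes <= nes).sum() / obs_den if obs_den else 1.0
        fdr[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    table["fdr_q"] = fdr
    table = table[["es", "nes", "p_perm", "fdr_q", "size_used", "direction"]]
    return EnrichmentResult(table)
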