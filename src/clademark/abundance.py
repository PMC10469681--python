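"""Genome relative abundance from mapped-read counts, and rank correlations.

Abundance is normalized as RPKM — reads per kilobase of genome per million
mapped reads: mapped / ((length/1e3) x (total/1e6)).  Rankings are unchanged
by the two scaling constants, so every downstream comparison is insensitive
to whether they are applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbundanceTable",
    "rpkm",
    "abundance_fractions",
    "spearman",
    "env_correlations",
    "bh_adjust",
]


@dataclass
class AbundanceTable:
    """Samples x genomes mapped-read counts with per-sample totals and genome lengths.

    ``counts`` rows are samples, columns genomes; ``totals`` is the per-sample
    metagenome size in reads (mapped counts may not exceed it); ``lengths`` is
    the genome length in bp.
    """

    counts: pd.DataFrame
    totals: pd.Series
    lengths: pd.Series

    def __post_init__(self):
        self.counts = self.counts.astype(int)
        self.totals = self.totals.astype(int)
        self.lengths = self.lengths.astype(int)
        if (self.counts.values < 0).any():
            raise ValueError("negative read counts")
        missing = set(self.counts.index) - set(self.totals.index)
        if missing:
            raise ValueError(f"samples without totals: {sorted(missing)}")
        missing = set(self.counts.columns) - set(self.lengths.index)
        if missing:
            raise ValueError(f"genomes without lengths: {sorted(missing)}")
        if (self.lengths <= 0).any():
            raise ValueError("genome lengths must be positive")
        mapped = self.counts.sum(axis=1)
        over = mapped > self.totals.loc[self.counts.index]
        if over.any():
            raise ValueError(f"mapped exceeds total for samples: {list(mapped.index[over])}")

    @classmethod
    def from_dicts(cls, counts, totals, lengths) -> "AbundanceTable":
        return cls(
            pd.DataFrame.from_dict(counts, orient="index").fillna(0),
            pd.Series(totals),
            pd.Series(lengths),
        )

    @property
    def samples(self) -> list:
        return list(self.counts.index)

    @property
    def genomes(self) -> list:
        return list(self.counts.columns)

    def rpkm(self) -> pd.DataFrame:
        """Per-sample, per-genome RPKM."""
        out = {}
        for s in self.samples:
            tot = int(self.totals[s])
            out[s] = {
                g: rpkm(int(self.counts.at[s, g]), int(self.lengths[g]), tot)
                for g in self.genomes
            }
        return pd.DataFrame.from_dict(out, orient="index")[self.genomes]


def rpkm(mapped: int, genome_len: int, total: int) -> float:
    """Reads per kilobase of genome per million mapped reads."""
    if genome_len <= 0:
        raise ValueError("genome length must be positive")
    if total <= 0:
        raise ValueError("total read count must be positive")
    if mapped < 0:
        raise ValueError("mapped read count must be nonnegative")
    return mapped / ((genome_len / 1e3) * (total / 1e6))


def abundance_fractions(table: AbundanceTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read fractions and RPKM-normalized relative shares.

    Returns ``(fractions, shares)``: ``fractions`` is mapped/total per sample
    and genome (rows sum to at most 1); ``shares`` renormalizes RPKM within
    each sample to sum to 1 over genomes with nonzero RPKM — an estimate of
    cell-level relative abundance.  A sample with no mapped reads gets NaN
    shares.
    """
    fractions = table.counts.div(table.totals.loc[table.counts.index], axis=0)
    r = table.rpkm()
    sums = r.sum(axis=1)
    shares = r.div(sums.where(sums > 0), axis=0)
    return fractions, shares


def _average_ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    p_method: str = "t",
    n_permutations: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rank correlation with pairwise missing-value removal.

    rho is the Pearson correlation of average ranks (ties get average rank).
    ``p_method='t'`` uses the t approximation; ``'permutation'`` a seeded
    permutation test (recommended below n=10).  Either input constant after
    missing removal leaves rho undefined and raises.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("inputs differ in length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >=3 complete pairs, have {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman rho undefined")
    rho, p_t = stats.spearmanr(x, y)
    rho = float(rho)
    if p_method == "t":
        return rho, float(p_t)
    if p_method != "permutation":
        raise ValueError(f"unknown p_method {p_method!r}")
    rng = np.random.default_rng(seed)
    rx = _average_ranks(x)
    ry = _average_ranks(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ry)
        if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
            hits += 1
    return rho, (hits + 1) / (n_permutations + 1)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvals, float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def env_correlations(
    abundance: pd.Series,
    env: pd.DataFrame,
    p_method: str = "t",
    seed: int = 0,
) -> pd.DataFrame:
    """Correlate a per-sample abundance vector with each environmental parameter.

    Missing values are removed pairwise per parameter; q is the BH-adjusted p.
    Parameters that end up constant or with fewer than 3 complete pairs are
    reported with NaN statistics rather than dropped.
    """
    rows = []
    for param in env.columns:
        joined = pd.concat([abundance, env[param]], axis=1, join="inner").dropna()
        try:
            rho, p = spearman(
                joined.iloc[:, 0].values, joined.iloc[:, 1].values,
                p_method=p_method, seed=seed,
            )
        except ValueError:
            rho, p = np.nan, np.nan
        rows.append({"parameter": param, "n": len(joined), "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["q"] = np.nan
    if valid.any():
        out.loc[valid, "q"] = bh_adjust(out.loc[valid, "p"].values)
    return out
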