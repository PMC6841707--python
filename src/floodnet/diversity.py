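"""Alpha diversity, dissimilarity, and beta-diversity partitioning.

Beta diversity is decomposed into its two antithetic phenomena following
Baselga: spatial *turnover* (species replacement between sites) and
*nestedness* (poorer communities being subsets of richer ones).  The
incidence mode partitions Sorensen dissimilarity into Simpson turnover plus a
nestedness remainder; the abundance mode partitions Bray-Curtis into
balanced-variation and abundance-gradient components.  Per-taxon and
per-sample contributions to beta diversity follow the Legendre-De Caceres
total-variance decomposition (SCBD/LCBD) on Hellinger-transformed abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from floodnet.core import CountTable, ValidationError


@dataclass
class BetaPartition:
    """Pairwise dissimilarity matrices: total = turnover + nestedness."""

    total: pd.DataFrame
    turnover: pd.DataFrame
    nestedness: pd.DataFrame
    mode: str  # "incidence" (Sorensen family) | "abundance" (Bray-Curtis family)


@dataclass
class TaxonContribution:
    """Shares of total beta diversity: per taxon (SCBD) and per sample (LCBD)."""

    taxon_share: pd.Series
    sample_share: pd.Series


def shannon_alpha(t: CountTable) -> pd.Series:
    """Shannon H' (natural log) per sample; all-zero samples reported as NaN."""
    c = t.counts.to_numpy(dtype=float)
    totals = c.sum(axis=0)
    out = np.full(c.shape[1], np.nan)
    for j in range(c.shape[1]):
        if totals[j] > 0:
            p = c[:, j][c[:, j] > 0] / totals[j]
            out[j] = -(p * np.log(p)).sum()
    return pd.Series(out, index=t.sample_ids, name="shannon_H")


def bray_curtis(t: CountTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples."""
    x = t.counts.to_numpy(dtype=float).T
    if x.shape[0] < 2:
        raise ValidationError("need >= 2 samples")
    if (x.sum(axis=1) == 0).any():
        raise ValidationError("sample with zero total reads")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=t.sample_ids, columns=t.sample_ids)


# ---------------------------------------------------------------------------
# Baselga pairwise partitioning
# ---------------------------------------------------------------------------

def _pairwise_incidence(x: np.ndarray):
    """Sorensen = Simpson turnover + nestedness, from shared/unique species counts."""
    pres = x > 0
    n = pres.shape[0]
    tot = np.full((n, n), 0.0)
    turn = np.full((n, n), 0.0)
    for j in range(n):
        for k in range(j + 1, n):
            a = np.sum(pres[j] & pres[k])
            b = np.sum(pres[j] & ~pres[k])
            c = np.sum(~pres[j] & pres[k])
            if a + b + c == 0:
                tot[j, k] = tot[k, j] = np.nan
                turn[j, k] = turn[k, j] = np.nan
                continue
            sor = (b + c) / (2 * a + b + c)
            sim = min(b, c) / (a + min(b, c)) if (a + min(b, c)) > 0 else 0.0
            tot[j, k] = tot[k, j] = sor
            turn[j, k] = turn[k, j] = sim
    return tot, turn, tot - turn


def _pairwise_abundance(x: np.ndarray):
    """Bray-Curtis = balanced-variation + abundance-gradient (Baselga 2013).

    With A = sum of per-species minima and B, C the site-exclusive abundance
    sums: d_BC = (B+C)/(2A+B+C); balanced component
    d_bal = min(B,C)/(A+min(B,C)); gradient component is the difference.
    """
    n = x.shape[0]
    tot = np.zeros((n, n))
    turn = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            mins = np.minimum(x[j], x[k])
            A = mins.sum()
            B = (x[j] - mins).sum()
            C = (x[k] - mins).sum()
            if 2 * A + B + C == 0:
                tot[j, k] = tot[k, j] = np.nan
                turn[j, k] = turn[k, j] = np.nan
                continue
            bc = (B + C) / (2 * A + B + C)
            bal = min(B, C) / (A + min(B, C)) if (A + min(B, C)) > 0 else 0.0
            tot[j, k] = tot[k, j] = bc
            turn[j, k] = turn[k, j] = bal
    return tot, turn, tot - turn


def beta_partition(t: CountTable, mode: str = "abundance") -> BetaPartition:
    """Pairwise beta-diversity partition into turnover and nestedness components."""
    x = t.counts.to_numpy(dtype=float).T
    if mode == "incidence":
        tot, turn, nest = _pairwise_incidence(x)
    elif mode == "abundance":
        tot, turn, nest = _pairwise_abundance(x)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    ids = t.sample_ids
    wrap = lambda m: pd.DataFrame(m, index=ids, columns=ids)
    return BetaPartition(total=wrap(tot), turnover=wrap(turn), nestedness=wrap(nest), mode=mode)


def multi_site_beta(t: CountTable, mode: str = "incidence") -> dict:
    """Baselga multi-site beta diversity over all samples of a group.

    Incidence mode returns the Sorensen-family statistics (beta_SOR =
    beta_SIM + beta_SNE); abundance mode the Bray-Curtis-family analogues.
    """
    x = t.counts.to_numpy(dtype=float).T
    n = x.shape[0]
    if n < 3:
        raise ValidationError("multi-site beta needs >= 3 samples")
    if mode == "incidence":
        pres = x > 0
        Si = pres.sum(axis=1)  # per-site richness
        ST = int(pres.any(axis=0).sum())  # pooled richness
        sum_min = 0.0
        sum_max = 0.0
        for j in range(n):
            for k in range(j + 1, n):
                b_jk = np.sum(pres[j] & ~pres[k])
                b_kj = np.sum(~pres[j] & pres[k])
                sum_min += min(b_jk, b_kj)
                sum_max += max(b_jk, b_kj)
        a_term = Si.sum() - ST  # sum of shared-with-pool overlaps
        if sum_min + sum_max + a_term == 0:
            return {"total": 0.0, "turnover": 0.0, "nestedness": 0.0, "mode": mode}
        beta_sim = sum_min / (a_term + sum_min)
        beta_sor = (sum_min + sum_max) / (2 * a_term + sum_min + sum_max)
        return {
            "total": float(beta_sor),
            "turnover": float(beta_sim),
            "nestedness": float(beta_sor - beta_sim),
            "mode": mode,
        }
    if mode == "abundance":
        sum_min_ab = 0.0
        sum_max_ab = 0.0
        sum_A = 0.0
        for j in range(n):
            for k in range(j + 1, n):
                mins = np.minimum(x[j], x[k])
                A = mins.sum()
                B = (x[j] - mins).sum()
                C = (x[k] - mins).sum()
                sum_A += A
                sum_min_ab += min(B, C)
                sum_max_ab += max(B, C)
        if sum_A + sum_min_ab + sum_max_ab == 0:
            return {"total": 0.0, "turnover": 0.0, "nestedness": 0.0, "mode": mode}
        bal = sum_min_ab / (sum_A + sum_min_ab)
        tot = (sum_min_ab + sum_max_ab) / (2 * sum_A + sum_min_ab + sum_max_ab)
        return {
            "total": float(tot),
            "turnover": float(bal),
            "nestedness": float(tot - bal),
            "mode": mode,
        }
    raise ValidationError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Contributions to beta diversity
# ---------------------------------------------------------------------------

def hellinger(x: np.ndarray) -> np.ndarray:
    """Hellinger transform: sqrt of row-normalised abundances (sites x species)."""
    totals = x.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValidationError("sample with zero total reads")
    return np.sqrt(x / totals)


def taxon_contributions(t: CountTable, transform: str = "hellinger") -> TaxonContribution:
    """SCBD/LCBD decomposition of total community variance.

    Columns of the (Hellinger-transformed) site-by-species matrix are
    centred; the total sum of squares then splits exactly by species (SCBD)
    and by site (LCBD), each share vector summing to 1.
    """
    x = t.counts.to_numpy(dtype=float).T  # sites x species
    if x.shape[0] < 3:
        raise ValidationError("need >= 3 samples")
    if transform == "hellinger":
        y = hellinger(x)
    elif transform == "none":
        y = x
    else:
        raise ValidationError(f"unknown transform {transform!r}")
    centred = y - y.mean(axis=0, keepdims=True)
    ss = centred**2
    ss_total = ss.sum()
    if ss_total <= 0:
        raise ValidationError("no variation among samples")
    return TaxonContribution(
        taxon_share=pd.Series(ss.sum(axis=0) / ss_total, index=t.taxon_ids, name="SCBD"),
        sample_share=pd.Series(ss.sum(axis=1) / ss_total, index=t.sample_ids, name="LCBD"),
    )


def guild_fractions(t: CountTable, guild: str) -> pd.Series:
    """Per-sample fraction of reads belonging to a guild."""
    if t.guild is None:
        raise ValidationError("count table has no guild annotation")
    known = set(t.guild.dropna().unique())
    if guild not in known:
        raise ValidationError(f"unknown guild {guild!r}; present: {sorted(known)}")
    members = t.guild == guild
    frac = t.counts.loc[members].sum(axis=0) / t.counts.sum(axis=0)
    return frac.rename(f"fraction_{guild}")
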