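"""Effective population size and the drift-barrier randomization critique.

Ne is estimated from neutral diversity and the mutation rate as
Ne = pi / (mu * D * (1 - pi)), with D = 2 for haploids and D = 4 for
diploids. Because mu enters the denominator, a negative correlation between
Ne and mu (or between Ne and the CDS mutation count, which is mu-derived)
can arise from the construction alone. The randomization critique permutes
diversity values among taxa, recomputes Ne, and asks (a) how often the
cross-taxa correlation comes out negative/significant under this null and
(b) how extreme the observed log-log slope is against it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

TAXA_COLUMNS = ["name", "pi", "mu", "D", "genome_size", "cds_mut"]


def estimate_ne(pi, mu, D) -> np.ndarray | float:
    """Ne = pi / (mu * D * (1 - pi)); strictly increasing in pi, strictly
    decreasing in mu and D."""
    pi = np.asarray(pi, dtype=float)
    mu = np.asarray(mu, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(pi <= 0) or np.any(pi >= 1):
        raise ValueError("pi must be in (0, 1)")
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if not np.all(np.isin(D, (2, 4))):
        raise ValueError("ploidy modifier D must be 2 (haploid) or 4 (diploid)")
    out = pi / (mu * D * (1.0 - pi))
    return float(out) if out.ndim == 0 else out


def load_taxa_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns name, pi, mu, D, genome_size, cds_mut."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TAXA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"taxa table missing columns: {sorted(missing)}")
    return df


def synthetic_taxa_table(
    n: int = 30, seed: int = 0
) -> pd.DataFrame:
    """Cross-taxa compendium with independent lognormal pi and mu, for
    exercising the randomization machinery without the published table."""
    rng = np.random.default_rng([int(seed), 977])
    pi = np.exp(rng.normal(np.log(5e-3), 1.0, size=n))
    pi = np.clip(pi, 1e-5, 0.5)
    mu = np.exp(rng.normal(np.log(1e-9), 1.2, size=n))
    D = rng.choice([2, 4], size=n)
    genome = np.exp(rng.normal(np.log(5e8), 1.5, size=n))
    cds_mut = mu * genome * 0.3 * np.exp(rng.normal(0, 0.3, size=n))
    return pd.DataFrame({
        "name": [f"taxon_{i}" for i in range(n)],
        "pi": pi, "mu": mu, "D": D,
        "genome_size": genome, "cds_mut": cds_mut,
    })


def _slope_r(logx: np.ndarray, logy: np.ndarray) -> tuple[float, float]:
    """(OLS slope, Pearson r) of logy on logx."""
    vx = logx - logx.mean()
    vy = logy - logy.mean()
    sxx = (vx ** 2).sum()
    syy = (vy ** 2).sum()
    sxy = (vx * vy).sum()
    slope = sxy / sxx
    r = sxy / np.sqrt(sxx * syy)
    return float(slope), float(r)


def drift_barrier_randomization(
    taxa: pd.DataFrame,
    m: int = 10_000,
    seed: int = 0,
    pin: str | None = None,
) -> dict:
    """Permute pi among taxa, recompute Ne, and summarize the null.

    For each of the two relationships — mutation rate vs Ne and CDS
    mutation count vs Ne, both on log10 axes — reports the observed slope,
    Pearson and Spearman correlations, the fraction of randomizations with
    a negative correlation, the fraction significantly negative at 0.05
    (t-approximation), and the slope-extremity p = (n+1)/(m+1) with n the
    randomizations whose slope is <= the observed. ``pin`` holds one
    taxon's pi fixed while the rest are permuted.
    """
    df = taxa.dropna(subset=["pi", "mu", "D", "cds_mut"]).reset_index(drop=True)
    n = len(df)
    if n < 3:
        raise ValueError("need at least 3 complete taxon records")
    pi = df["pi"].to_numpy(float)
    mu = df["mu"].to_numpy(float)
    D = df["D"].to_numpy(float)
    cds = df["cds_mut"].to_numpy(float)
    log_mu = np.log10(mu)
    log_cds = np.log10(cds)

    r_crit = -stats.t.ppf(0.025, n - 2)  # |t| threshold at alpha=0.05
    r_thresh = r_crit / np.sqrt(n - 2 + r_crit ** 2)

    def analyse(pi_vec):
        ne = estimate_ne(pi_vec, mu, D)
        log_ne = np.log10(ne)
        out = {}
        for key, y in (("mu_vs_ne", log_mu), ("cds_vs_ne", log_cds)):
            slope, r = _slope_r(log_ne, y)
            rho = stats.spearmanr(log_ne, y).statistic
            out[key] = (slope, r, float(rho))
        return out

    observed = analyse(pi)

    rng = np.random.default_rng([int(seed), 607])
    pin_idx = None
    if pin is not None:
        match = np.flatnonzero(df["name"].to_numpy() == pin)
        if match.size == 0:
            raise ValueError(f"taxon {pin!r} not in table")
        pin_idx = int(match[0])

    tallies = {
        key: {"negative": 0, "significant": 0, "slope_le_obs": 0}
        for key in ("mu_vs_ne", "cds_vs_ne")
    }
    for _ in range(m):
        if pin_idx is None:
            perm_pi = rng.permutation(pi)
        else:
            others = np.delete(np.arange(n), pin_idx)
            perm_pi = pi.copy()
            perm_pi[others] = pi[others][rng.permutation(n - 1)]
        res = analyse(perm_pi)
        for key in tallies:
            slope, r, _ = res[key]
            if r < 0:
                tallies[key]["negative"] += 1
            if r < -r_thresh:
                tallies[key]["significant"] += 1
            if slope <= observed[key][0]:
                tallies[key]["slope_le_obs"] += 1

    report = {"m": int(m), "seed": int(seed), "n_taxa": int(n)}
    for key in ("mu_vs_ne", "cds_vs_ne"):
        slope, r, rho = observed[key]
        t = tallies[key]
        report[key] = {
            "observed_slope": slope,
            "observed_pearson": r,
            "observed_spearman": rho,
            "frac_negative": t["negative"] / m,
            "frac_significant_negative": t["significant"] / m,
            "n_significant_negative": t["significant"],
            "slope_extremity_p": (t["slope_le_obs"] + 1) / (m + 1),
        }
    return report
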