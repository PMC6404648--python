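"""F_ST outlier detection and FDR control.

Two scans over per-SNP differentiation:

* :func:`fdist_scan` — coalescent island-model null envelopes of F_ST
  conditional on heterozygosity (FDIST approach): migration is calibrated so
  the mean simulated F_ST matches the observed multilocus value, one
  segregating site is dropped on each simulated genealogy, and conditional
  quantiles come from sliding heterozygosity windows of simulated loci.
* :func:`bayescan_like` — Bayesian logistic decomposition
  logit(F_ST^ij) = alpha_i + beta_j (Beaumont-Balding / BayeScan model) with
  reversible-jump moves toggling the locus effect alpha_i, posterior
  inclusion probabilities and local-FDR q-values.

Plus :func:`storey_qvalues`, the Storey pi0 / q-value FDR procedure at a
single lambda.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .differentiation import multilocus_fst, per_site_fst

__all__ = [
    "simulate_island_snps",
    "calibrate_island_migration",
    "FdistResult",
    "fdist_scan",
    "BayeScanResult",
    "bayescan_like",
    "FdrSummary",
    "storey_qvalues",
]


# --- island-model SNP null ---------------------------------------------------


def simulate_island_snps(
    demes: int,
    M: float,
    sample_sizes: list[int],
    reps: int,
    seed=None,
    backend: str = "fast",
) -> tuple[np.ndarray, np.ndarray]:
    """(F_ST, H_e) of ``reps`` single-SNP loci under the finite island model.

    Each sampled group occupies its own deme (sizes in ``sample_sizes``); one
    mutation is placed on the genealogy proportional to branch length, giving
    a biallelic SNP whose F_ST and total heterozygosity are recorded.
    ``backend='fast'`` (default) is the compiled engine;
    ``backend='native'`` uses the pure-Python reference engine (slower, used
    for cross-validation).
    """
    if len(sample_sizes) > demes:
        raise ValueError("more sampled groups than demes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = np.asarray(sample_sizes, int)
    if backend == "native":
        from .coalescent import mutate_infinite_sites, simulate_island

        counts = np.empty((reps, len(sizes)))
        for r in range(reps):
            g = simulate_island(demes, M, list(sizes), seed=rng)
            sim = mutate_infinite_sites(g, L=10, S=1, seed=rng)
            col = sim.matrix[:, 0]
            start = 0
            for j, nj in enumerate(sizes):
                counts[r, j] = col[start:start + nj].sum()
                start += nj
    else:
        from ._island_fast import island_snp_counts

        counts = island_snp_counts(
            demes, M, sizes, reps, int(rng.integers(2**31 - 1))
        ).astype(float)
    fst, he = per_site_fst(counts, sizes)
    return fst, he


def calibrate_island_migration(
    target_fst: float,
    demes: int,
    sample_sizes: list[int],
    seed=None,
    sims_per_eval: int = 500,
    iterations: int = 11,
) -> float:
    """1-D search for the migration rate M whose mean simulated F_ST matches
    ``target_fst`` (bisection on log M; common seeds across evaluations)."""
    if target_fst <= 0:
        raise ValueError("observed multilocus F_ST <= 0: degenerate null")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eval_seed = int(rng.integers(2**31 - 1))
    sizes = np.asarray(sample_sizes, float)

    def mean_fst(log_m: float) -> float:
        from ._island_fast import island_snp_counts

        counts = island_snp_counts(
            demes, math.exp(log_m), sample_sizes, sims_per_eval, eval_seed
        ).astype(float)
        return multilocus_fst(counts, sizes)

    # F_ST below ~1/300 is indistinguishable from panmixia at these sample
    # sizes; the bracket caps migration there to keep event counts bounded
    lo, hi = math.log(0.05), math.log(300.0)
    # mean F_ST decreases with M
    f_lo, f_hi = mean_fst(lo), mean_fst(hi)
    if target_fst >= f_lo:
        return math.exp(lo)
    if target_fst <= f_hi:
        return math.exp(hi)
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if mean_fst(mid) > target_fst:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi))


@dataclass
class FdistResult:
    table: pd.DataFrame  # per SNP: fst, he, p, q50, q95, q99, flag95, flag99
    M: float
    demes: int
    reps: int
    target_fst: float
    seed: int | None


def fdist_scan(
    fst_obs: np.ndarray,
    he_obs: np.ndarray,
    sample_sizes: list[int],
    demes: int = 100,
    reps: int = 20000,
    window: int = 500,
    seed: int | None = None,
    target_fst: float | None = None,
    counts_obs: np.ndarray | None = None,
    sizes_obs: np.ndarray | None = None,
    trim_iterations: int = 1,
) -> FdistResult:
    """FDIST-style F_ST outlier scan.

    Simulates ``reps`` island-model SNPs at migration calibrated to the
    observed multilocus F_ST, then compares each observed SNP with the
    simulated loci closest in heterozygosity (a window of ``window`` loci,
    widened symmetrically if the tails are short).

    The conditional null of single-SNP F_ST given heterozygosity is heavily
    discrete (low-count SNPs carry point masses), so the reported ``p`` is
    the exact-size randomized tie-broken empirical p-value
    (#{F_sim > F_obs} + U * (#{F_sim = F_obs} + 1)) / (B + 1), which is
    uniform under the null; ``p_upper`` is the conservative non-randomized
    fraction of window loci with F_ST >= observed.  Flags mark SNPs with
    p <= 0.05 and p <= 0.01 (the conditional 95% / 99% thresholds).

    When ``counts_obs``/``sizes_obs`` are supplied the calibration target is
    the weighted (ratio-of-sums) multilocus F_ST, and ``trim_iterations``
    rounds of outlier trimming are applied: SNPs flagged at the 99% level
    are removed from the target estimate and the scan repeats, so strong
    outliers do not inflate the neutral envelope.
    """
    fst_obs = np.asarray(fst_obs, float)
    he_obs = np.asarray(he_obs, float)
    ok = ~np.isnan(fst_obs) & ~np.isnan(he_obs)
    if target_fst is None:
        if counts_obs is not None:
            # preferred: weighted (ratio-of-sums) multilocus F_ST
            target_fst = multilocus_fst(counts_obs, sizes_obs)
        else:
            target_fst = float(np.nanmean(fst_obs[ok]))
    if target_fst <= 0:
        raise ValueError("observed multilocus F_ST <= 0: degenerate null")
    rng = np.random.default_rng(seed)

    def scan_once(target: float) -> tuple[pd.DataFrame, float]:
        M = calibrate_island_migration(target, demes, sample_sizes, seed=rng)
        fst_sim, he_sim = simulate_island_snps(demes, M, sample_sizes, reps,
                                               seed=rng)
        keep = ~np.isnan(fst_sim)
        fst_sim, he_sim = fst_sim[keep], he_sim[keep]
        order = np.argsort(he_sim)
        fst_sim, he_sim = fst_sim[order], he_sim[order]
        m = len(fst_sim)
        w = min(window, m)
        half = w // 2
        rows = []
        for i in range(len(fst_obs)):
            if not ok[i]:
                rows.append(dict(fst=fst_obs[i], he=he_obs[i], p=np.nan,
                                 p_upper=np.nan, q50=np.nan, q95=np.nan,
                                 q99=np.nan, flag95=False, flag99=False))
                continue
            # exact-class conditioning where possible: with complete data He
            # is a bijection of the folded allele count, so an equal-He block
            # of simulated loci IS the exact conditional null.  Mixing
            # neighbouring classes into a window fattens the upper tail
            # (higher-He classes have wider F_ST nulls) and mis-sizes the
            # test, so the sliding window is only a fallback for sparse
            # classes.
            c_lo = int(np.searchsorted(he_sim, he_obs[i], side="left"))
            c_hi = int(np.searchsorted(he_sim, he_obs[i], side="right"))
            if c_hi - c_lo >= min(200, w):
                win = fst_sim[c_lo:c_hi]
            else:
                c = (c_lo + c_hi) // 2
                lo = max(0, min(c - half, m - w))
                win = fst_sim[lo:lo + w]
            q50, q95, q99 = np.quantile(win, [0.5, 0.95, 0.99])
            gt = int(np.sum(win > fst_obs[i]))
            eq = int(np.sum(win == fst_obs[i]))
            p_upper = (gt + eq + 1.0) / (len(win) + 1.0)
            p = (gt + rng.random() * (eq + 1.0)) / (len(win) + 1.0)
            rows.append(dict(fst=fst_obs[i], he=he_obs[i], p=float(p),
                             p_upper=float(p_upper),
                             q50=float(q50), q95=float(q95), q99=float(q99),
                             flag95=bool(p <= 0.05), flag99=bool(p <= 0.01)))
        return pd.DataFrame(rows), M

    table, M = scan_once(target_fst)
    if counts_obs is not None:
        for _ in range(trim_iterations):
            flagged = table["flag99"].to_numpy(bool)
            if not flagged.any():
                break
            keep_idx = ~flagged
            new_target = multilocus_fst(counts_obs[keep_idx],
                                        np.broadcast_to(
                                            np.asarray(sizes_obs, float),
                                            counts_obs.shape)[keep_idx])
            if new_target <= 0 or abs(new_target - target_fst) < 1e-3:
                break
            target_fst = new_target
            table, M = scan_once(target_fst)
    return FdistResult(table, M, demes, reps, target_fst, seed)


# --- BayeScan-style reversible-jump scan ------------------------------------


def _bb_loglik(a, n, mu, theta):
    """Beta-binomial log-likelihood with Beta(theta*mu, theta*(1-mu))."""
    a1 = theta * mu
    b1 = theta * (1.0 - mu)
    return (
        gammaln(n + 1) - gammaln(a + 1) - gammaln(n - a + 1)
        + gammaln(a + a1) + gammaln(n - a + b1) - gammaln(n + a1 + b1)
        + gammaln(a1 + b1) - gammaln(a1) - gammaln(b1)
    )


@dataclass
class BayeScanResult:
    table: pd.DataFrame  # per SNP: inclusion_prob, alpha_mean, q, selected
    beta: np.ndarray
    acceptance: dict[str, float]
    settings: dict


def bayescan_like(
    counts: np.ndarray,
    sizes: np.ndarray,
    maf_filter: float = 0.05,
    burn_in: int = 50000,
    samples: int = 5000,
    thin: int = 10,
    pilot_runs: int = 20,
    pilot_length: int = 5000,
    prior_odds: float = 10.0,
    q_threshold: float = 0.05,
    seed: int | None = None,
) -> BayeScanResult:
    """Reversible-jump MCMC scan for locus-specific selection effects.

    Model: derived counts a_ij ~ BetaBinomial with population-specific
    F_ST^ij, logit(F_ST^ij) = alpha_i * delta_i + beta_j; priors
    alpha_i ~ N(0,1), beta_j ~ N(-1, 1.8^2), ancestral frequency p_i uniform;
    prior odds ``prior_odds`` for the neutral model (P(delta=1) =
    1/(1+prior_odds)).  Pilot runs tune random-walk widths toward 25-45%
    acceptance.  SNPs failing the MAF filter are excluded from the model and
    absent from the output table (their index is not reported).

    Returns posterior inclusion probabilities, posterior mean alpha (over
    included iterations), and local-FDR q-values (cumulative mean of
    1 - inclusion probability in decreasing-probability order).
    """
    counts = np.asarray(counts, float)
    sizes = np.asarray(sizes, float)
    if sizes.ndim == 1:
        sizes = np.broadcast_to(sizes, counts.shape).copy()
    S, d = counts.shape
    if d < 2:
        raise ValueError("need >= 2 populations")
    pooled = counts.sum(axis=1) / sizes.sum(axis=1)
    maf = np.minimum(pooled, 1.0 - pooled)
    keep = maf > maf_filter
    idx_kept = np.where(keep)[0]
    a = counts[keep]
    n = sizes[keep]
    S = a.shape[0]
    if S == 0:
        raise ValueError("no SNPs pass the MAF filter")
    rng = np.random.default_rng(seed)

    # state
    p = (a.sum(axis=1) + 1.0) / (n.sum(axis=1) + 2.0)
    alpha = np.zeros(S)
    delta = np.zeros(S, dtype=bool)
    beta = np.full(d, -1.0)
    pi1 = 1.0 / (1.0 + prior_odds)
    log_prior_ratio_add = math.log(pi1 / (1.0 - pi1))

    def loglik_matrix(pv, av, dv, bv):
        logit_f = np.where(dv[:, None], av[:, None], 0.0) + bv[None, :]
        f = expit(logit_f)
        f = np.clip(f, 1e-9, 1.0 - 1e-9)
        theta = 1.0 / f - 1.0
        mu = np.clip(pv, 1e-9, 1.0 - 1e-9)[:, None]
        return _bb_loglik(a, n, mu, theta)

    L = loglik_matrix(p, alpha, delta, beta)
    rowsum = L.sum(axis=1)

    widths = {"p": 0.4, "alpha": 0.6, "beta": 0.25}
    acc = {k: 0 for k in ("p", "alpha", "beta", "jump")}
    tries = {k: 0 for k in ("p", "alpha", "beta", "jump")}

    def update_p():
        nonlocal p, L, rowsum
        x = np.log(p / (1 - p))
        xn = x + rng.normal(0, widths["p"], S)
        pn = expit(xn)
        Ln = loglik_matrix(pn, alpha, delta, beta)
        rn = Ln.sum(axis=1)
        # logit RW on uniform(p): Jacobian p(1-p)
        log_r = rn - rowsum + np.log(pn * (1 - pn)) - np.log(p * (1 - p))
        accept = np.log(rng.random(S)) < log_r
        p[accept] = pn[accept]
        L[accept] = Ln[accept]
        rowsum[accept] = rn[accept]
        acc["p"] += int(accept.sum())
        tries["p"] += S

    def update_alpha():
        nonlocal alpha, L, rowsum
        on = np.where(delta)[0]
        if len(on) == 0:
            return
        an = alpha.copy()
        an[on] += rng.normal(0, widths["alpha"], len(on))
        Ln = loglik_matrix(p, an, delta, beta)
        rn = Ln.sum(axis=1)
        log_r = rn - rowsum - 0.5 * (an**2 - alpha**2)
        accept = np.zeros(S, bool)
        accept[on] = np.log(rng.random(len(on))) < log_r[on]
        alpha[accept] = an[accept]
        L[accept] = Ln[accept]
        rowsum[accept] = rn[accept]
        acc["alpha"] += int(accept.sum())
        tries["alpha"] += len(on)

    def update_jump():
        nonlocal alpha, delta, L, rowsum
        dn = ~delta
        an = np.where(dn & ~delta, rng.normal(0, 1, S), alpha)
        Ln = loglik_matrix(p, an, dn, beta)
        rn = Ln.sum(axis=1)
        # proposal for alpha = prior, so only the model prior odds remain
        log_r = rn - rowsum + np.where(dn, log_prior_ratio_add,
                                       -log_prior_ratio_add)
        accept = np.log(rng.random(S)) < log_r
        delta[accept] = dn[accept]
        alpha[accept] = an[accept]
        L[accept] = Ln[accept]
        rowsum[accept] = rn[accept]
        acc["jump"] += int(accept.sum())
        tries["jump"] += S

    def _loglik_column(bj: float, j: int) -> np.ndarray:
        logit_f = np.where(delta, alpha, 0.0) + bj
        f = np.clip(expit(logit_f), 1e-9, 1.0 - 1e-9)
        theta = 1.0 / f - 1.0
        mu = np.clip(p, 1e-9, 1.0 - 1e-9)
        return _bb_loglik(a[:, j], n[:, j], mu, theta)

    def update_beta():
        # a beta_j move only touches likelihood column j
        nonlocal beta, L, rowsum
        for j in range(d):
            bj_new = beta[j] + rng.normal(0, widths["beta"])
            col_new = _loglik_column(bj_new, j)
            log_r = (col_new.sum() - L[:, j].sum()
                     - ((bj_new + 1) ** 2 - (beta[j] + 1) ** 2) / (2 * 1.8**2))
            tries["beta"] += 1
            if math.log(rng.random()) < log_r:
                beta[j] = bj_new
                rowsum += col_new - L[:, j]
                L[:, j] = col_new
                acc["beta"] += 1

    def sweep():
        update_p()
        update_alpha()
        update_jump()
        update_beta()

    # pilot tuning
    for _ in range(pilot_runs):
        for k in acc:
            acc[k] = tries[k] = 0
        for _ in range(pilot_length):
            sweep()
        for k in ("p", "alpha", "beta"):
            if tries[k] == 0:
                continue
            rate = acc[k] / tries[k]
            if rate < 0.25:
                widths[k] *= 0.7
            elif rate > 0.45:
                widths[k] *= 1.4

    for k in acc:
        acc[k] = tries[k] = 0
    for _ in range(burn_in):
        sweep()

    inc = np.zeros(S)
    alpha_sum = np.zeros(S)
    alpha_n = np.zeros(S)
    beta_sum = np.zeros(d)
    kept = 0
    for it in range(samples * thin):
        sweep()
        if it % thin == 0:
            inc += delta
            alpha_sum[delta] += alpha[delta]
            alpha_n[delta] += 1
            beta_sum += beta
            kept += 1
    pip = inc / kept
    alpha_mean = np.where(alpha_n > 0, alpha_sum / np.maximum(alpha_n, 1), 0.0)

    order = np.argsort(-pip, kind="stable")
    qv = np.empty(S)
    csum = np.cumsum(1.0 - pip[order])
    qv[order] = csum / (np.arange(S) + 1.0)
    rates = {k: (acc[k] / tries[k] if tries[k] else float("nan")) for k in acc}
    table = pd.DataFrame(
        dict(
            snp_index=idx_kept,
            inclusion_prob=pip,
            alpha_mean=alpha_mean,
            q=qv,
            selected=qv < q_threshold,
        )
    )
    return BayeScanResult(
        table, beta_sum / max(kept, 1), rates,
        dict(burn_in=burn_in, samples=samples, thin=thin,
             pilot_runs=pilot_runs, pilot_length=pilot_length,
             prior_odds=prior_odds, maf_filter=maf_filter, seed=seed),
    )


# --- Storey q-values ---------------------------------------------------------


@dataclass
class FdrSummary:
    p_values: np.ndarray
    lam: float
    pi0: float
    q_values: np.ndarray


def storey_qvalues(p_values, lam: float = 0.15, pi0: float | None = None) -> FdrSummary:
    """Storey pi0 estimate at a single lambda and step-up q-values.

    pi0 = min(1, #{p > lambda} / (m (1 - lambda))) unless supplied;
    q(p_(i)) = min_{j >= i} pi0 * m * p_(j) / j.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = len(p)
    if pi0 is None:
        pi0 = min(1.0, float(np.sum(p > lam)) / (m * (1.0 - lam)))
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / (np.arange(m) + 1.0)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return FdrSummary(p, lam, pi0, q)
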