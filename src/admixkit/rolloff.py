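"""Admixture dating from the decay of admixture LD with genetic distance.

When two diverged populations mix n generations ago, alleles that entered
on the same ancestral haplotype remain associated over genetic distances
of order 1/n Morgans: for two SNPs d Morgans apart the probability that
an admixed chromosome carries them on an unrecombined ancestry segment is
e^{-nd}. The dating procedure exploits this by correlating, within bins
of genetic distance, a pairwise LD score with the product of per-SNP
weights that measure allele-frequency differentiation between the two
ancestral reference populations. The bin correlation decays as
A e^{-nd}; fitting the exponential yields the admixture date n in
generations, with a standard error from a weighted delete-one-chromosome
jackknife.

The pipeline is exposed both as individual stages (:func:`snp_weights`,
:func:`pair_ld_score`, :func:`bin_pairs`, :func:`fit_exponential`) and as
the :class:`Rolloff` model whose :meth:`Rolloff.fit` orchestrates them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .data import FreqTable, GenotypeMatrix, SnpTable, allele_frequencies
from .jackknife import weighted_jackknife

__all__ = [
    "Rolloff",
    "RolloffResults",
    "RolloffFitError",
    "snp_weights",
    "pair_ld_score",
    "bin_pairs",
    "fit_exponential",
    "rolloff_date",
    "estimate_bias",
    "BiasEstimate",
]

# accumulator channels per distance bin
_N, _SZ, _SW, _SZZ, _SWW, _SZW = range(6)
R_CLIP = 0.9
MIN_PAIR_SAMPLES = 4


class RolloffFitError(RuntimeError):
    """Raised when no admixture-LD decay can be fitted."""


def snp_weights(freq_a, freq_b, normalized: bool = True) -> np.ndarray:
    """Per-SNP ancestry-informativeness weights from two reference panels.

    With empirical reference frequencies a and b and p = (a+b)/2, the
    weight is ``(a - b) / sqrt(p (1 - p))``. SNPs where p is 0 or 1 (or a
    frequency is missing) get NaN and are excluded downstream. With
    ``normalized=False`` the plain difference ``a - b`` is used — the
    fallback when no surrogate ancestral panels are available and only a
    quantity proportional to the frequency difference can be formed.
    """
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    diff = a - b
    if not normalized:
        return diff
    p = 0.5 * (a + b)
    denom = p * (1.0 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, diff / np.sqrt(np.maximum(denom, 1e-300)), np.nan)
    return w


def pair_ld_score(g1, g2):
    """Fisher-stabilised LD score for one SNP pair.

    Computes the Pearson correlation r of the diploid genotypes over the
    samples non-missing at both markers, clips r to [-0.9, 0.9], and
    returns ``z = atanh(r) * sqrt(N - 3)`` together with N. Returns None
    (the pair is skipped) when fewer than 4 samples remain or either
    genotype vector is constant.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    mask = ~(np.isnan(g1) | np.isnan(g2))
    n = int(mask.sum())
    if n < MIN_PAIR_SAMPLES:
        return None
    x, y = g1[mask], g2[mask]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(max(r, -R_CLIP), R_CLIP)
    return float(np.arctanh(r) * np.sqrt(n - 3)), n


def _pairs_for_lag(G, S1, S2, V, k):
    """Row-wise Pearson r between SNP rows i and i+k, honouring missingness.

    G is the SNP x sample genotype matrix with NaN for missing, V its
    validity mask, S1/S2 cached row sums of G and G**2 over valid entries.
    Returns (r, N) arrays of length S-k with NaN where the pair is skipped.
    """
    X, Y = G[:-k], G[k:]
    VX, VY = V[:-k], V[k:]
    if VX.all() and VY.all():
        n = np.full(X.shape[0], X.shape[1], dtype=float)
        sx, sy = S1[:-k], S1[k:]
        sxx, syy = S2[:-k], S2[k:]
        sxy = np.einsum("ij,ij->i", X, Y)
    else:
        both = VX & VY
        n = both.sum(axis=1).astype(float)
        Xz = np.where(both, X, 0.0)
        Yz = np.where(both, Y, 0.0)
        sx = Xz.sum(axis=1)
        sy = Yz.sum(axis=1)
        sxx = np.einsum("ij,ij->i", Xz, Xz)
        syy = np.einsum("ij,ij->i", Yz, Yz)
        sxy = np.einsum("ij,ij->i", Xz, Yz)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx**2
        vary = n * syy - sy**2
        r = cov / np.sqrt(varx * vary)
    r[(n < MIN_PAIR_SAMPLES) | (varx <= 0) | (vary <= 0)] = np.nan
    return r, n


def _accumulate_chromosome(G, gpos, w, bin_width_m, d_max_m):
    """Streaming per-bin sums of (z, ww) moments for one chromosome.

    Returns an accumulator array of shape (n_bins, 6) holding per bin the
    pair count and the sums z, ww, z^2, ww^2, z*ww needed to form Pearson
    correlations, for every within-chromosome pair with 0 < d <= d_max.
    """
    n_bins = int(np.ceil(d_max_m / bin_width_m))
    acc = np.zeros((n_bins, 6))
    S = G.shape[0]
    if S < 2:
        return acc
    V = ~np.isnan(G)
    Gz = np.where(V, G, 0.0)
    S1 = Gz.sum(axis=1)
    S2 = (Gz**2).sum(axis=1)
    for k in range(1, S):
        d = gpos[k:] - gpos[:-k]
        if d.min() > d_max_m:
            break
        r, n = _pairs_for_lag(G, S1, S2, V, k)
        ww = w[:-k] * w[k:]
        keep = (d > 0) & (d <= d_max_m) & ~np.isnan(r) & ~np.isnan(ww)
        if not keep.any():
            continue
        rk = np.clip(r[keep], -R_CLIP, R_CLIP)
        z = np.arctanh(rk) * np.sqrt(n[keep] - 3.0)
        wk = ww[keep]
        bins = np.minimum((d[keep] / bin_width_m).astype(np.int64), n_bins - 1)
        acc[:, _N] += np.bincount(bins, minlength=n_bins)
        acc[:, _SZ] += np.bincount(bins, weights=z, minlength=n_bins)
        acc[:, _SW] += np.bincount(bins, weights=wk, minlength=n_bins)
        acc[:, _SZZ] += np.bincount(bins, weights=z * z, minlength=n_bins)
        acc[:, _SWW] += np.bincount(bins, weights=wk * wk, minlength=n_bins)
        acc[:, _SZW] += np.bincount(bins, weights=z * wk, minlength=n_bins)
    return acc


def _bins_from_acc(acc, bin_width_m) -> pd.DataFrame:
    """Per-bin Pearson correlation between LD score and weight product."""
    n = acc[:, _N]
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * acc[:, _SZW] - acc[:, _SZ] * acc[:, _SW]
        varz = n * acc[:, _SZZ] - acc[:, _SZ] ** 2
        varw = n * acc[:, _SWW] - acc[:, _SW] ** 2
        corr = cov / np.sqrt(varz * varw)
    usable = (n >= 2) & np.isfinite(corr)
    mids = (np.arange(acc.shape[0]) + 0.5) * bin_width_m
    return pd.DataFrame(
        {
            "d_mid": mids,  # Morgans
            "bin_cm": mids * 100.0,
            "corr": np.where(usable, corr, np.nan),
            "n_pairs": n.astype(np.int64),
        }
    )


def bin_pairs(pairs, bin_width_cm: float = 0.1, d_max_cm: float = 30.0) -> pd.DataFrame:
    """Bin an iterable of ``(d_morgans, z, ww)`` pairs into distance bins.

    Returns a DataFrame with bin midpoints (Morgans and cM), the Pearson
    correlation between z and ww within each bin, and the pair count; bins
    with fewer than 2 pairs get NaN correlation.
    """
    if bin_width_cm <= 0:
        raise ValueError("bin width must be positive")
    bw = bin_width_cm / 100.0
    dmax = d_max_cm / 100.0
    n_bins = int(np.ceil(dmax / bw))
    acc = np.zeros((n_bins, 6))
    for d, z, ww in pairs:
        if not (0 < d <= dmax):
            continue
        b = min(int(d / bw), n_bins - 1)
        acc[b] += (1.0, z, ww, z * z, ww * ww, z * ww)
    return _bins_from_acc(acc, bw)


def fit_exponential(
    bins: pd.DataFrame,
    d_min_cm: float = 0.5,
    d_max_cm: float = 30.0,
    weight_by_pairs: bool = False,
    with_offset: bool = True,
):
    """Least-squares fit of ``corr(d) = A exp(-n d) + c`` over usable bins.

    Distances are in Morgans so the fitted rate n is in generations.
    The additive constant c (on by default) absorbs the distance-
    independent component of the weighted LD correlation contributed by
    variation in genome-wide ancestry proportion across individuals;
    without it the fitted rate is biased downward, badly so for cohorts
    with heterogeneous ancestry. Pass ``with_offset=False`` for the bare
    exponential. Initial values come from a log-linear regression on the
    positive bins. Raises :class:`RolloffFitError` when fewer than 5
    usable bins lie in the window or the fitted decay is degenerate.
    """
    sel = bins[
        (bins["bin_cm"] >= d_min_cm)
        & (bins["bin_cm"] <= d_max_cm)
        & np.isfinite(bins["corr"])
    ]
    if len(sel) < 5:
        raise RolloffFitError(
            f"only {len(sel)} usable bins in [{d_min_cm}, {d_max_cm}] cM; need >= 5"
        )
    d = sel["d_mid"].to_numpy()
    y = sel["corr"].to_numpy()
    pos = y > 0
    if pos.sum() < 2:
        raise RolloffFitError("no detectable admixture LD decay (no positive bins)")
    slope, intercept = np.polyfit(d[pos], np.log(y[pos]), 1)
    n0 = max(-slope, 1.0)
    a0 = float(np.exp(intercept))
    sigma = None
    if weight_by_pairs:
        npairs = sel["n_pairs"].to_numpy().astype(float)
        sigma = 1.0 / np.sqrt(np.maximum(npairs, 1.0))

    if with_offset:
        model = lambda x, A, n, c: A * np.exp(-n * x) + c
        p0 = (a0, n0, 0.0)
    else:
        model = lambda x, A, n: A * np.exp(-n * x)
        p0 = (a0, n0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, d, y, p0=p0, sigma=sigma, maxfev=10000)
    except RuntimeError as exc:
        raise RolloffFitError("no detectable admixture LD decay (fit failed)") from exc
    amplitude, rate = float(popt[0]), float(popt[1])
    if rate <= 1e-6 or amplitude <= 0:
        raise RolloffFitError(
            "no detectable admixture LD decay (non-positive fitted rate or amplitude)"
        )
    return rate, amplitude


def fit_double_exponential(bins, d_min_cm=0.5, d_max_cm=30.0):
    """Fit ``A1 e^{-n1 d} + A2 e^{-n2 d}``. Experimental: sums of
    exponentials are notoriously ill-conditioned and this rarely separates
    two events reliably; prefer the single-exponential fit."""
    sel = bins[
        (bins["bin_cm"] >= d_min_cm)
        & (bins["bin_cm"] <= d_max_cm)
        & np.isfinite(bins["corr"])
    ]
    if len(sel) < 8:
        raise RolloffFitError("too few usable bins for a two-exponential fit")
    d = sel["d_mid"].to_numpy()
    y = sel["corr"].to_numpy()
    n1, a1 = None, None
    try:
        n1, a1 = fit_exponential(bins, d_min_cm, d_max_cm)
    except RolloffFitError:
        n1, a1 = 30.0, max(float(y.max()), 1e-3)
    model = lambda x, A1, r1, A2, r2: A1 * np.exp(-r1 * x) + A2 * np.exp(-r2 * x)
    p0 = (a1 / 2, n1 / 2, a1 / 2, n1 * 2)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, d, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RolloffFitError("two-exponential fit failed") from exc
    pairs = sorted([(popt[1], popt[0]), (popt[3], popt[2])])
    return pairs  # [(rate_slow, amp), (rate_fast, amp)]


@dataclass
class RolloffResults:
    """Fitted admixture date with jackknife uncertainty and the decay curve."""

    date: float  # generations
    se: float
    amplitude: float
    bins: pd.DataFrame
    fit_range_cm: tuple
    n_snps: int
    n_chromosomes: int
    loo_dates: dict = field(default_factory=dict, repr=False)

    @property
    def n(self):  # alias used in the admixture-LD literature
        return self.date

    def years(self, years_per_generation: float = 29.0) -> float:
        return self.date * years_per_generation

    def summary(self) -> str:
        lo, hi = self.fit_range_cm
        return "\n".join(
            [
                "Admixture-LD date estimate",
                f"  date  {self.date:.1f} +/- {self.se:.1f} generations",
                f"  (~{self.years():.0f} years at 29 years/generation)",
                f"  amplitude  {self.amplitude:.4g}",
                f"  fit window  [{lo:g}, {hi:g}] cM over "
                f"{int(np.isfinite(self.bins['corr']).sum())} usable bins",
                f"  SNPs {self.n_snps}   chromosomes {self.n_chromosomes}",
            ]
        )

    def plot(self, ax=None, show_fit: bool = True):
        """Decay of the weighted LD correlation with genetic distance."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        usable = np.isfinite(self.bins["corr"])
        ax.plot(
            self.bins.loc[usable, "bin_cm"],
            self.bins.loc[usable, "corr"],
            ".",
            color="0.4",
            label="binned correlation",
        )
        if show_fit:
            lo, hi = self.fit_range_cm
            x = np.linspace(lo, hi, 200)
            ax.plot(
                x,
                self.amplitude * np.exp(-self.date * x / 100.0),
                "r-",
                label=f"fit: {self.date:.1f} ± {self.se:.1f} generations",
            )
        ax.set_xlabel("genetic distance (cM)")
        ax.set_ylabel("weighted LD correlation")
        ax.legend()
        return ax

    def __repr__(self):
        return f"<RolloffResults date={self.date:.1f}±{self.se:.1f} generations>"


class Rolloff:
    """Admixture-LD dating model for one target population.

    Parameters
    ----------
    genotypes : GenotypeMatrix or float ndarray
        Diploid genotypes of the admixed target samples (SNP x sample;
        NaN or 9 for missing). With a :class:`GenotypeMatrix` and a
        *target* label, the relevant columns are selected automatically.
    freq_a, freq_b : arrays of float
        Reference-panel allele frequencies for the two proposed ancestral
        populations, one value per SNP (NaN where unavailable).
    snps : SnpTable, optional
        Required when *genotypes* is a bare array.
    target : str, optional
        Population label selecting target columns from a GenotypeMatrix.
    bin_cm, min_cm, max_cm : float
        Distance-bin width and the fit window. Bins below ``min_cm``
        (default 0.5 cM) are excluded from fitting because background LD
        confounds admixture LD at short range.
    normalized_weights : bool
        Use the variance-normalised weight (default) or the plain
        frequency difference.
    """

    def __init__(
        self,
        genotypes,
        freq_a,
        freq_b,
        snps: SnpTable | None = None,
        target: str | None = None,
        bin_cm: float = 0.1,
        min_cm: float = 0.5,
        max_cm: float = 30.0,
        normalized_weights: bool = True,
        weight_fit_by_pairs: bool = False,
        with_offset: bool = True,
    ):
        if isinstance(genotypes, GenotypeMatrix):
            snps = genotypes.snps
            if target is not None:
                G = genotypes.population_view(target)
            else:
                G = genotypes.as_float()
        else:
            G = np.asarray(genotypes, dtype=float)
            G = np.where(G == 9, np.nan, G)
            if snps is None:
                raise ValueError("snps table required with a bare genotype array")
        if G.shape[0] != len(snps):
            raise ValueError("genotype rows do not match the SNP table")
        if bin_cm <= 0:
            raise ValueError("bin width must be positive")
        self.G = G
        self.snps = snps
        self.weights = snp_weights(freq_a, freq_b, normalized=normalized_weights)
        self.bin_cm = bin_cm
        self.min_cm = min_cm
        self.max_cm = max_cm
        self.weight_fit_by_pairs = weight_fit_by_pairs
        self.with_offset = with_offset

    @classmethod
    def from_dataset(cls, genotypes: GenotypeMatrix, target, ref_a, ref_b, **kwargs):
        """Build the model from one labelled dataset: the target columns
        supply genotypes and the two reference populations supply the
        weight frequencies."""
        if target in (ref_a, ref_b):
            raise ValueError("target population must be disjoint from the references")
        freqs = allele_frequencies(genotypes, [ref_a, ref_b])
        return cls(
            genotypes,
            freqs.freq(ref_a),
            freqs.freq(ref_b),
            target=target,
            **kwargs,
        )

    def _chromosome_accumulators(self):
        bw = self.bin_cm / 100.0
        dmax = self.max_cm / 100.0
        accs, snp_counts, chroms = [], [], []
        gpos = self.snps.genetic_pos
        for chrom, sl in self.snps.chromosome_slices():
            w = self.weights[sl]
            keep = np.isfinite(w)
            accs.append(
                _accumulate_chromosome(
                    self.G[sl][keep], gpos[sl][keep], w[keep], bw, dmax
                )
            )
            snp_counts.append(int(keep.sum()))
            chroms.append(chrom)
        return chroms, accs, snp_counts

    def fit(self) -> RolloffResults:
        """Run the full pipeline and jackknife the date over chromosomes."""
        chroms, accs, snp_counts = self._chromosome_accumulators()
        if len(chroms) < 2:
            raise ValueError("admixture-LD dating needs at least 2 chromosomes")
        total = np.sum(accs, axis=0)
        bw = self.bin_cm / 100.0
        bins = _bins_from_acc(total, bw)
        rate, amplitude = fit_exponential(
            bins,
            self.min_cm,
            self.max_cm,
            weight_by_pairs=self.weight_fit_by_pairs,
            with_offset=self.with_offset,
        )
        loo_dates, loo_used, loo_weights, failed = {}, [], [], []
        for j, chrom in enumerate(chroms):
            sub = _bins_from_acc(total - accs[j], bw)
            try:
                r_j, _ = fit_exponential(
                    sub,
                    self.min_cm,
                    self.max_cm,
                    weight_by_pairs=self.weight_fit_by_pairs,
                    with_offset=self.with_offset,
                )
            except RolloffFitError:
                failed.append(chrom)
                continue
            loo_dates[chrom] = r_j
            if snp_counts[j] > 0:  # zero-weight chromosomes cannot enter the SE
                loo_used.append(r_j)
                loo_weights.append(snp_counts[j])
        if failed:
            warnings.warn(
                f"leave-one-out fit failed for chromosome(s) {failed}; "
                "excluded from the jackknife"
            )
        if len(loo_used) < 2:
            raise RolloffFitError(
                "fewer than 2 successful leave-one-chromosome-out fits"
            )
        _, se = weighted_jackknife(
            rate, np.array(loo_used), np.array(loo_weights, float)
        )
        return RolloffResults(
            date=rate,
            se=se,
            amplitude=amplitude,
            bins=bins,
            fit_range_cm=(self.min_cm, self.max_cm),
            n_snps=int(np.isfinite(self.weights).sum()),
            n_chromosomes=len(chroms),
            loo_dates=loo_dates,
        )


def rolloff_date(genotypes, freq_a, freq_b, snps=None, target=None, **kwargs):
    """One-call orchestration: weights -> pair LD scores -> bins -> fit -> SE."""
    return Rolloff(
        genotypes, freq_a, freq_b, snps=snps, target=target, **kwargs
    ).fit()


@dataclass
class BiasEstimate:
    """Simulation-calibrated bias of an admixture-LD date estimate."""

    bias: float
    corrected_date: float
    replicate_dates: np.ndarray
    true_date: float

    def summary(self) -> str:
        return (
            f"bias {self.bias:+.1f} generations over "
            f"{self.replicate_dates.size} replicates at true date "
            f"{self.true_date:g}; corrected date {self.corrected_date:.1f}"
        )


def estimate_bias(
    date: float,
    theta: float,
    n_diploid: int,
    n_replicates: int = 100,
    seed: int = 0,
    estimated_date: float | None = None,
    pool_kwargs: dict | None = None,
    rolloff_kwargs: dict | None = None,
) -> BiasEstimate:
    """Matched-simulation bias correction for an admixture-LD date.

    Simulates *n_replicates* cohorts at the empirically estimated
    parameters (*date* in generations, mixture proportion *theta*,
    *n_diploid* samples), re-estimates the date on each, and reports
    ``bias = mean(replicate dates) - date`` and the corrected estimate
    ``estimated_date - bias`` (*estimated_date* defaults to *date*).
    Fails if more than half the replicates cannot be fitted.
    """
    from . import simulate  # deferred: avoids an import cycle

    if estimated_date is None:
        estimated_date = date
    rng = np.random.default_rng(seed)
    pool_kwargs = dict(pool_kwargs or {})
    rolloff_kwargs = dict(rolloff_kwargs or {})
    dates = []
    failures = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(2**31 - 1))
        try:
            res = simulate.simulate_and_date(
                lam=date,
                theta=theta,
                n_diploid=n_diploid,
                seed=rep_seed,
                pool_kwargs=pool_kwargs,
                rolloff_kwargs=rolloff_kwargs,
            )
            dates.append(res.date)
        except (RolloffFitError, ValueError):
            failures += 1
    if failures > n_replicates / 2:
        raise RolloffFitError(
            f"{failures}/{n_replicates} bias-simulation replicates failed"
        )
    dates = np.asarray(dates)
    bias = float(dates.mean() - date)
    return BiasEstimate(
        bias=bias,
        corrected_date=float(estimated_date - bias),
        replicate_dates=dates,
        true_date=float(date),
    )
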