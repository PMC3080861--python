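"""Synthetic ancestral haplotype pools and mosaic admixed genomes.

The generator stands in for phased reference panels so that every method
in the package can be validated end-to-end without external data. Two
diverged ancestral pools are produced by a Balding-Nichols model: each
SNP draws an ancestral frequency, and each population's frequency is a
Beta deviate dispersed around it with a spread set by the target F_ST.
Haplotypes are sampled from the population frequencies through a
first-order Gaussian copula along each chromosome, giving background LD
that decays on a configurable genetic-distance scale.

Admixed genomes are mosaics of donor-haplotype segments. Walking each
haploid chromosome marker by marker, ancestry is resampled with
probability 1 - e^{-lambda * g} (g the inter-marker distance in Morgans,
lambda the generations since mixture) and each resampling event draws a
fresh Bernoulli(theta) ancestry and a fresh donor haplotype, taking care
that no donor chromosomal segment is used twice. Single-pulse,
double-pulse and continuous gene-flow histories are supported, and the
true local-ancestry tracts are retained for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import FreqTable, GenotypeMatrix, IndividualTable, SnpTable

__all__ = [
    "HaplotypePool",
    "AdmixedCohort",
    "SimulationParams",
    "generate_snp_table",
    "ancestral_frequencies",
    "drift_frequencies",
    "haplotypes_from_frequencies",
    "generate_ancestral_pools",
    "generate_panel_with_outgroups",
    "reference_frequencies",
    "simulate_pulse",
    "simulate_double_pulse",
    "simulate_continuous",
    "simulate",
    "simulate_and_date",
    "simulate_and_estimate_ancestry",
    "simulate_null_tree_freqs",
    "hudson_fst",
    "beta_theta",
]

# study-condition defaults for the synthetic genome
DEFAULT_N_SNPS = 22_000
DEFAULT_N_CHROMOSOMES = 22
DEFAULT_CHROM_LENGTH_M = 1.0
DEFAULT_FST = 0.15
DEFAULT_LD_SCALE_CM = 0.05
DEFAULT_POOL_HAPLOTYPES = 200


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class HaplotypePool:
    """Phased haplotypes of one ancestral population."""

    haplotypes: np.ndarray  # (n_haplotypes, n_snps) in {0,1}
    snps: SnpTable
    population: str
    pop_freq: np.ndarray | None = None  # generating population frequencies
    ancestral_freq: np.ndarray | None = None

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.snps):
            raise ValueError("haplotype matrix shape does not match the SNP table")
        if self.haplotypes.max(initial=0) > 1:
            raise ValueError("haplotype entries must be 0/1")

    @property
    def n_haplotypes(self):
        return self.haplotypes.shape[0]

    @property
    def sample_freq(self) -> np.ndarray:
        """Reference-allele frequency observed in the pool itself."""
        return self.haplotypes.mean(axis=0)


@dataclass
class AdmixedCohort:
    """Simulated admixed diploids with their true local-ancestry tracts."""

    genotypes: GenotypeMatrix
    tracts: pd.DataFrame  # haploid, chromosome, ancestry, snp/genetic extent
    haploid_fraction: np.ndarray  # realized pool-A fraction per haploid
    theta: np.ndarray  # intended pool-A proportion per diploid

    @property
    def ancestry_fraction(self) -> np.ndarray:
        """Realized pool-A ancestry fraction per diploid individual."""
        return 0.5 * (self.haploid_fraction[0::2] + self.haploid_fraction[1::2])


@dataclass
class SimulationParams:
    """Admixture history: schedule plus cohort size and seed.

    ``schedule`` is ``"pulse"`` (theta, lam), ``"double_pulse"``
    (lam1, theta1, lam2, theta2) or ``"continuous"`` (a, b, theta with
    per-generation migration solved so total migrant ancestry is theta).
    """

    theta: float = 0.2
    lam: float = 10.0
    schedule: str = "pulse"
    n_diploid: int = 10
    seed: int | None = None
    lam2: float | None = None
    theta2: float | None = None
    a: int | None = None
    b: int | None = None


def generate_snp_table(
    n_snps: int = DEFAULT_N_SNPS,
    n_chromosomes: int = DEFAULT_N_CHROMOSOMES,
    chrom_length_m: float = DEFAULT_CHROM_LENGTH_M,
) -> SnpTable:
    """Uniformly spaced SNPs over ``n_chromosomes`` of ``chrom_length_m``."""
    per = np.full(n_chromosomes, n_snps // n_chromosomes)
    per[: n_snps % n_chromosomes] += 1
    ids, chroms, phys, gpos = [], [], [], []
    for c in range(n_chromosomes):
        s = int(per[c])
        spacing = chrom_length_m / s
        g = (np.arange(s) + 0.5) * spacing
        ids.extend(f"snp{c + 1}_{i}" for i in range(s))
        chroms.extend([c + 1] * s)
        phys.extend(((np.arange(s) + 1) * 1000).tolist())
        gpos.extend(g.tolist())
    return SnpTable(ids, chroms, phys, gpos)


def ancestral_frequencies(n_snps, rng=None, low=0.1, high=0.9) -> np.ndarray:
    """Ancestral allele frequencies, uniform on [low, high]."""
    return _rng(rng).uniform(low, high, size=n_snps)


def drift_frequencies(freq, c, rng=None) -> np.ndarray:
    """Balding-Nichols drift: Beta deviates around *freq* with spread *c*.

    ``c`` plays the role of an F_ST-like drift parameter: the child
    frequencies have mean *freq* and variance ``c * freq * (1 - freq)``.
    """
    if not 0 < c < 1:
        raise ValueError("drift parameter must lie in (0, 1)")
    freq = np.asarray(freq, dtype=float)
    scale = (1.0 - c) / c
    return _rng(rng).beta(freq * scale, (1.0 - freq) * scale)


def haplotypes_from_frequencies(
    pop_freq, snps: SnpTable, n_haplotypes, ld_scale_cm=0.0, rng=None
) -> np.ndarray:
    """Sample haplotypes matching per-SNP frequencies with background LD.

    With ``ld_scale_cm == 0`` sites are independent. Otherwise each
    haplotype follows a stationary Gaussian AR(1) process along the
    chromosome whose autocorrelation decays as ``exp(-d / ld_scale)``;
    thresholding the latent Gaussian at the per-SNP frequency quantile
    yields alleles with the requested marginals and LD that decays on the
    chosen genetic-distance scale.
    """
    rng = _rng(rng)
    pop_freq = np.asarray(pop_freq, dtype=float)
    S = len(snps)
    if ld_scale_cm <= 0:
        return (rng.random((n_haplotypes, S)) < pop_freq).astype(np.uint8)
    scale_m = ld_scale_cm / 100.0
    thresh = norm.ppf(np.clip(pop_freq, 1e-12, 1 - 1e-12))
    out = np.empty((n_haplotypes, S), dtype=np.uint8)
    gpos = snps.genetic_pos
    for _, sl in snps.chromosome_slices():
        g = gpos[sl]
        rho = np.exp(-np.diff(g) / scale_m)
        innov = np.sqrt(1.0 - rho**2)
        z = np.empty((n_haplotypes, g.size))
        z[:, 0] = rng.standard_normal(n_haplotypes)
        noise = rng.standard_normal((n_haplotypes, g.size - 1))
        for j in range(1, g.size):
            z[:, j] = rho[j - 1] * z[:, j - 1] + innov[j - 1] * noise[:, j - 1]
        out[:, sl] = z < thresh[sl]
    return out


def generate_ancestral_pools(
    n_haplotypes: int = DEFAULT_POOL_HAPLOTYPES,
    n_snps: int = DEFAULT_N_SNPS,
    n_chromosomes: int = DEFAULT_N_CHROMOSOMES,
    chrom_length_m: float = DEFAULT_CHROM_LENGTH_M,
    fst: float = DEFAULT_FST,
    ld_scale_cm: float = DEFAULT_LD_SCALE_CM,
    seed=None,
):
    """Two diverged ancestral haplotype pools plus their SNP table.

    Population frequencies for pools "A" and "B" are independent
    Balding-Nichols draws around a shared ancestral frequency with drift
    parameter *fst*, so the Hudson F_ST between the emitted population
    frequencies is *fst* in expectation.
    """
    if not 0 < fst <= 0.5:
        raise ValueError("fst target must lie in (0, 0.5]")
    rng = _rng(seed)
    snps = generate_snp_table(n_snps, n_chromosomes, chrom_length_m)
    anc = ancestral_frequencies(len(snps), rng)
    pools = []
    for name in ("A", "B"):
        p = drift_frequencies(anc, fst, rng)
        haps = haplotypes_from_frequencies(p, snps, n_haplotypes, ld_scale_cm, rng)
        pools.append(
            HaplotypePool(haps, snps, name, pop_freq=p, ancestral_freq=anc)
        )
    return pools[0], pools[1], snps


def reference_frequencies(pool: HaplotypePool, n_haplotypes: int = 100, rng=None):
    """Allele frequencies of an independent reference panel.

    Draws a fresh sample of *n_haplotypes* from the pool's generating
    population frequencies — a reference panel from the same population
    but statistically independent of the donor haplotypes, as when weights
    come from a non-overlapping dataset.
    """
    if pool.pop_freq is None:
        raise ValueError("pool lacks generating population frequencies")
    rng = _rng(rng)
    counts = rng.binomial(n_haplotypes, pool.pop_freq)
    return counts / n_haplotypes, np.full(len(pool.pop_freq), n_haplotypes)


def generate_panel_with_outgroups(
    n_haplotypes: int = DEFAULT_POOL_HAPLOTYPES,
    n_snps: int = DEFAULT_N_SNPS,
    n_chromosomes: int = DEFAULT_N_CHROMOSOMES,
    chrom_length_m: float = DEFAULT_CHROM_LENGTH_M,
    fst: float = DEFAULT_FST,
    ld_scale_cm: float = DEFAULT_LD_SCALE_CM,
    outgroup_drift: float = 0.10,
    outgroup_alleles: int = 40,
    seed=None,
):
    """Two mixing pools plus two outgroup panels for f4-ratio estimation.

    The mixing populations A and B each accumulate their drift from the
    shared ancestral frequency in two Balding-Nichols steps whose
    composition matches the pairwise *fst* target; one outgroup panel
    hangs off each population's mid-branch node, so the outgroup
    frequency difference shares drift with the A-B contrast — the
    configuration that makes the f4 ratio informative. Outgroup
    frequencies are observed through binomial sampling of
    *outgroup_alleles* alleles.

    Returns ``(pool_a, pool_b, outgroup_freqs, snps)`` where
    ``outgroup_freqs`` maps ``"O1"``/``"O2"`` to (p, n_alleles) arrays.
    """
    if not 0 < fst <= 0.5:
        raise ValueError("fst target must lie in (0, 0.5]")
    rng = _rng(seed)
    snps = generate_snp_table(n_snps, n_chromosomes, chrom_length_m)
    anc = ancestral_frequencies(len(snps), rng)
    # two drift steps of size f compose to 1-(1-f)^2 = fst
    f_step = 1.0 - np.sqrt(1.0 - fst)
    pools, outgroups = [], {}
    for name, og in (("A", "O1"), ("B", "O2")):
        mid = drift_frequencies(anc, f_step, rng)
        p = drift_frequencies(mid, f_step, rng)
        haps = haplotypes_from_frequencies(p, snps, n_haplotypes, ld_scale_cm, rng)
        pools.append(HaplotypePool(haps, snps, name, pop_freq=p, ancestral_freq=anc))
        og_pop = drift_frequencies(mid, outgroup_drift, rng)
        og_p = rng.binomial(outgroup_alleles, og_pop) / outgroup_alleles
        outgroups[og] = (og_p, np.full(len(snps), outgroup_alleles))
    return pools[0], pools[1], outgroups, snps


def beta_theta(mean: float, sd: float):
    """Per-individual mixture proportions from a Beta distribution.

    Returns a callable drawing one proportion per individual; e.g.
    ``beta_theta(0.2, 0.1)`` emulates a cohort whose members vary in
    ancestry around 20%.
    """
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    if nu <= 0:
        raise ValueError("sd too large for a Beta distribution with this mean")
    alpha, beta = mean * nu, (1.0 - mean) * nu

    def draw(rng, size):
        return _rng(rng).beta(alpha, beta, size=size)

    return draw


def _resolve_theta(theta, n_diploid, rng):
    if callable(theta):
        vals = np.asarray(theta(rng, n_diploid), dtype=float)
    else:
        vals = np.asarray(theta, dtype=float)
        if vals.ndim == 0:
            vals = np.full(n_diploid, float(vals))
    if vals.shape != (n_diploid,):
        raise ValueError("theta must be scalar, per-diploid sequence, or callable")
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("mixture proportions must lie in [0, 1]")
    return vals


def _walk_events(gpos, rate, rng):
    """Boolean resampling events between consecutive markers at *rate*."""
    if rate <= 0:
        return np.zeros(gpos.size - 1, dtype=bool)
    p = 1.0 - np.exp(-rate * np.diff(gpos))
    return rng.random(gpos.size - 1) < p


def _segments_from_events(events):
    """Segment id per marker from inter-marker event indicators."""
    seg = np.zeros(events.size + 1, dtype=np.int64)
    np.cumsum(events, out=seg[1:])
    return seg


class _DonorLedger:
    """Tracks which donor-haplotype intervals have been copied already."""

    def __init__(self, pool_sizes):
        # per pool: {haplotype index: list of (start, stop) snp intervals}
        self.used = [dict() for _ in pool_sizes]
        self.sizes = pool_sizes

    def assign(self, pool_idx, start, stop, rng):
        order = rng.permutation(self.sizes[pool_idx])
        used = self.used[pool_idx]
        for h in order:
            intervals = used.get(int(h))
            if intervals is None:
                used[int(h)] = [(start, stop)]
                return int(h)
            if all(stop <= s or start >= e for s, e in intervals):
                intervals.append((start, stop))
                return int(h)
        raise RuntimeError(
            "ancestral haplotype pool exhausted: no unused donor segment "
            "available; rerun with large_n=True or enlarge the pools"
        )


def _compose_cohort(
    pools, snps, n_diploid, rng, segment_fn, theta_record, large_n=False
):
    """Shared mosaic assembly: per haploid chromosome, *segment_fn* yields
    (donor_segment_id_per_snp, ancestry_bool_per_snp); donor haplotype
    segments are then copied without reuse and tracts recorded."""
    n_hap = 2 * n_diploid
    S = len(snps)
    gpos = snps.genetic_pos
    hap_alleles = np.empty((n_hap, S), dtype=np.uint8)
    hap_anc_sum = np.zeros(n_hap)
    tract_rows = []

    chrom_slices = list(snps.chromosome_slices())
    ledgers = {
        chrom: _DonorLedger([p.n_haplotypes for p in pools]) for chrom, _ in chrom_slices
    }
    if large_n:
        for p in pools:
            if n_hap > p.n_haplotypes:
                raise RuntimeError(
                    f"large_n mode needs at least {n_hap} haplotypes per pool, "
                    f"pool {p.population!r} has {p.n_haplotypes}"
                )
        large_donors = [rng.permutation(p.n_haplotypes)[:n_hap] for p in pools]

    for hap in range(n_hap):
        for chrom, sl in chrom_slices:
            g = gpos[sl]
            seg_id, anc = segment_fn(hap, chrom, g)
            hap_anc_sum[hap] += anc.sum()
            # copy donor segments
            boundaries = np.flatnonzero(np.diff(seg_id)) + 1
            starts = np.concatenate([[0], boundaries])
            stops = np.concatenate([boundaries, [g.size]])
            base = sl.start
            for lo, hi in zip(starts, stops):
                pool_idx = 0 if anc[lo] else 1
                if large_n:
                    donor = int(large_donors[pool_idx][hap])
                else:
                    donor = ledgers[chrom].assign(pool_idx, base + lo, base + hi, rng)
                hap_alleles[hap, base + lo : base + hi] = pools[pool_idx].haplotypes[
                    donor, base + lo : base + hi
                ]
            # record ancestry tracts (merging same-ancestry donor segments)
            a_bound = np.flatnonzero(np.diff(anc.astype(np.int8))) + 1
            t_starts = np.concatenate([[0], a_bound])
            t_stops = np.concatenate([a_bound, [g.size]])
            # an ancestry switch happened somewhere between the flanking
            # markers: place the boundary uniformly inside the interval so
            # tract lengths are free of the marker-lattice artifact; terminal
            # tracts run to the marker span ends and are flagged censored
            cuts = g[a_bound - 1] + rng.random(a_bound.size) * (
                g[a_bound] - g[a_bound - 1]
            )
            bound_pos = {int(i): c for i, c in zip(a_bound, cuts)}
            for lo, hi in zip(t_starts, t_stops):
                start_g = g[lo] if lo == 0 else bound_pos[int(lo)]
                end_g = g[hi - 1] if hi == g.size else bound_pos[int(hi)]
                tract_rows.append(
                    (
                        hap,
                        chrom,
                        "A" if anc[lo] else "B",
                        base + lo,
                        base + hi - 1,
                        start_g,
                        end_g,
                        lo != 0 and hi != g.size,
                    )
                )

    tracts = pd.DataFrame(
        tract_rows,
        columns=[
            "haploid",
            "chromosome",
            "ancestry",
            "start_snp",
            "end_snp",
            "start_g",
            "end_g",
            "interior",
        ],
    )
    genotype_values = (hap_alleles[0::2] + hap_alleles[1::2]).T.astype(np.int8)
    individuals = IndividualTable(
        [f"adm{i}" for i in range(n_diploid)], ["admixed"] * n_diploid
    )
    return AdmixedCohort(
        genotypes=GenotypeMatrix(genotype_values, snps, individuals),
        tracts=tracts,
        haploid_fraction=hap_anc_sum / S,
        theta=theta_record,
    )


def simulate_pulse(
    pool_a: HaplotypePool,
    pool_b: HaplotypePool,
    theta,
    lam: float,
    n_diploid: int = 10,
    seed=None,
    large_n: bool = False,
) -> AdmixedCohort:
    """Single-pulse admixture *lam* generations ago.

    *theta* is the probability a sampled haplotype derives from
    ``pool_a`` — a scalar, a per-diploid sequence, or a callable such as
    :func:`beta_theta` for individual-level variation. Both haploids of a
    diploid share that individual's proportion.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    rng = _rng(seed)
    snps = pool_a.snps
    thetas = _resolve_theta(theta, n_diploid, rng)

    def segment_fn(hap, chrom, g):
        th = thetas[hap // 2]
        events = _walk_events(g, lam, rng)
        seg_id = _segments_from_events(events)
        draws = rng.random(seg_id[-1] + 1) < th
        return seg_id, draws[seg_id]

    return _compose_cohort(
        (pool_a, pool_b), snps, n_diploid, rng, segment_fn, thetas, large_n
    )


def simulate_double_pulse(
    pool_a: HaplotypePool,
    pool_b: HaplotypePool,
    lam1: float,
    theta1: float,
    lam2: float,
    theta2: float,
    n_diploid: int = 10,
    seed=None,
    large_n: bool = False,
) -> AdmixedCohort:
    """Two sequential admixture pulses.

    A theta1/(1-theta1) mixture of pools A and B formed *lam1* generations
    ago; *lam2* generations ago that population received fresh pool-B
    ancestry so that a fraction *theta2* of lineages descend from the
    first mixture. Expected final pool-A ancestry is ``theta1 * theta2``.
    Requires ``lam1 > lam2``.
    """
    if not lam1 > lam2 > 0:
        raise ValueError("need lam1 > lam2 > 0")
    rng = _rng(seed)
    snps = pool_a.snps

    def segment_fn(hap, chrom, g):
        outer_ev = _walk_events(g, lam2, rng)
        inner_ev = _walk_events(g, lam1 - lam2, rng) | outer_ev
        outer_seg = _segments_from_events(outer_ev)
        inner_seg = _segments_from_events(inner_ev)
        from_first = (rng.random(outer_seg[-1] + 1) < theta2)[outer_seg]
        inner_a = (rng.random(inner_seg[-1] + 1) < theta1)[inner_seg]
        anc = from_first & inner_a
        return inner_seg, anc

    thetas = np.full(n_diploid, theta1 * theta2)
    return _compose_cohort(
        (pool_a, pool_b), snps, n_diploid, rng, segment_fn, thetas, large_n
    )


def simulate_continuous(
    pool_a: HaplotypePool,
    pool_b: HaplotypePool,
    a: int,
    b: int,
    total_theta: float,
    n_diploid: int = 10,
    seed=None,
    large_n: bool = False,
) -> AdmixedCohort:
    """Continuous gene flow from pool B into pool A over [a, b] generations ago.

    In each of the ``b - a + 1`` generations a fraction m of lineages is
    replaced by fresh pool-B migrants, with m solved from
    ``(1 - m)^(b - a + 1) = 1 - total_theta`` so the expected final
    migrant (pool-B) ancestry is *total_theta*. Each migrant cohort's
    tracts break down at the rate set by its own residence time.
    """
    if not (0 < a <= b):
        raise ValueError("need generation interval 0 < a <= b")
    if not 0 < total_theta < 1:
        raise ValueError("total_theta must lie in (0, 1)")
    rng = _rng(seed)
    snps = pool_a.snps
    n_gen = b - a + 1
    m = 1.0 - (1.0 - total_theta) ** (1.0 / n_gen)
    gens = list(range(b, a - 1, -1))  # oldest first; newest overwrites

    def segment_fn(hap, chrom, g):
        entry = np.zeros(g.size, dtype=np.int64)  # 0 = native pool A
        events_by_gen = {}
        for t in gens:
            ev = _walk_events(g, t, rng)
            events_by_gen[t] = ev
            seg = _segments_from_events(ev)
            migrant = (rng.random(seg[-1] + 1) < m)[seg]
            entry[migrant] = t
        native_ev = _walk_events(g, b, rng)  # native lineages recombine too
        boundary = np.zeros(g.size - 1, dtype=bool)
        boundary |= entry[1:] != entry[:-1]
        for t in gens:
            boundary |= (entry[1:] == t) & events_by_gen[t]
        boundary |= (entry[1:] == 0) & native_ev
        seg_id = _segments_from_events(boundary)
        anc = entry == 0  # True = pool A
        return seg_id, anc

    thetas = np.full(n_diploid, 1.0 - total_theta)
    return _compose_cohort(
        (pool_a, pool_b), snps, n_diploid, rng, segment_fn, thetas, large_n
    )


def simulate(pool_a, pool_b, params: SimulationParams) -> AdmixedCohort:
    """Dispatch on :class:`SimulationParams.schedule`."""
    if params.schedule == "pulse":
        return simulate_pulse(
            pool_a, pool_b, params.theta, params.lam, params.n_diploid, params.seed
        )
    if params.schedule == "double_pulse":
        return simulate_double_pulse(
            pool_a,
            pool_b,
            params.lam,
            params.theta,
            params.lam2,
            params.theta2,
            params.n_diploid,
            params.seed,
        )
    if params.schedule == "continuous":
        return simulate_continuous(
            pool_a, pool_b, params.a, params.b, params.theta,
            params.n_diploid, params.seed,
        )
    raise ValueError(f"unknown schedule {params.schedule!r}")


def simulate_and_date(
    lam,
    theta,
    n_diploid=10,
    seed=None,
    schedule="pulse",
    pool_kwargs=None,
    rolloff_kwargs=None,
    n_ref_haplotypes=100,
    **schedule_kwargs,
):
    """Generate pools, simulate a cohort, and date it — one replicate.

    Weights use independent reference panels resampled from the pools'
    generating population frequencies. Returns the
    :class:`admixkit.rolloff.RolloffResults` of the fitted date.
    """
    from .rolloff import Rolloff  # deferred: avoids an import cycle

    rng = _rng(seed)
    pool_kwargs = dict(pool_kwargs or {})
    pool_a, pool_b, snps = generate_ancestral_pools(seed=rng, **pool_kwargs)
    if schedule == "pulse":
        cohort = simulate_pulse(pool_a, pool_b, theta, lam, n_diploid, rng)
    elif schedule == "double_pulse":
        cohort = simulate_double_pulse(
            pool_a, pool_b, lam, theta,
            schedule_kwargs["lam2"], schedule_kwargs["theta2"], n_diploid, rng,
        )
    elif schedule == "continuous":
        cohort = simulate_continuous(
            pool_a, pool_b, schedule_kwargs["a"], schedule_kwargs["b"],
            theta, n_diploid, rng,
        )
    else:
        raise ValueError(f"unknown schedule {schedule!r}")
    fa, _ = reference_frequencies(pool_a, n_ref_haplotypes, rng)
    fb, _ = reference_frequencies(pool_b, n_ref_haplotypes, rng)
    model = Rolloff(
        cohort.genotypes.as_float(), fa, fb, snps=snps, **dict(rolloff_kwargs or {})
    )
    return model.fit()


def simulate_and_estimate_ancestry(
    theta=0.2,
    lam=50.0,
    n_diploid=10,
    seed=None,
    panel_kwargs=None,
    n_ref_haplotypes=100,
    block_size_cm=5.0,
):
    """Simulate an admixed cohort and estimate its ancestry by f4 ratio.

    Builds mixing pools with outgroup panels, simulates a pulse cohort
    with pool-A proportion *theta*, and returns the
    :class:`admixkit.fstats.AncestryResults` for the cohort, using the
    outgroups plus independent reference panels of the two pools.
    """
    from .data import allele_frequencies  # local alias for clarity
    from .fstats import F4Ratio
    from .jackknife import block_partition

    rng = _rng(seed)
    pool_a, pool_b, outgroups, snps = generate_panel_with_outgroups(
        seed=rng, **dict(panel_kwargs or {})
    )
    cohort = simulate_pulse(pool_a, pool_b, theta, lam, n_diploid, rng)
    fa, na = reference_frequencies(pool_a, n_ref_haplotypes, rng)
    fb, nb = reference_frequencies(pool_b, n_ref_haplotypes, rng)
    xf = allele_frequencies(cohort.genotypes)
    freqs = FreqTable.from_arrays(
        {
            "O1": outgroups["O1"],
            "O2": outgroups["O2"],
            "A": (fa, na),
            "B": (fb, nb),
            "X": (xf.freq("admixed"), xf.counts("admixed")),
        }
    )
    return F4Ratio(
        freqs, "O1", "O2", "A", "B", "X",
        block_ids=block_partition(snps, block_size_cm),
    ).fit()


def simulate_null_tree_freqs(
    n_snps: int = 50_000,
    drift: float = 0.02,
    n_alleles: int = 200,
    n_blocks: int = 100,
    seed=None,
):
    """Sampled allele frequencies under the unadmixed tree ((A,B),(C,D)).

    Frequencies drift independently down the tree (Balding-Nichols steps
    of size *drift*) and are then observed through binomial sampling of
    *n_alleles* alleles per population. Returns ``(FreqTable, block_ids)``
    with contiguous blocks for the jackknife; SNPs are unlinked so any
    contiguous partition is valid.
    """
    rng = _rng(seed)
    anc = ancestral_frequencies(n_snps, rng)
    node_ab = drift_frequencies(anc, drift, rng)
    node_cd = drift_frequencies(anc, drift, rng)
    p_cols, n_cols = {}, {}
    for name, node in (("A", node_ab), ("B", node_ab), ("C", node_cd), ("D", node_cd)):
        p_pop = drift_frequencies(node, drift, rng)
        p_cols[name] = rng.binomial(n_alleles, p_pop) / n_alleles
        n_cols[name] = np.full(n_snps, n_alleles)
    freqs = FreqTable(pd.DataFrame(p_cols), pd.DataFrame(n_cols))
    block_ids = (np.arange(n_snps) * n_blocks) // n_snps
    return freqs, block_ids


def hudson_fst(p1, p2, n1=None, n2=None) -> float:
    """Hudson's F_ST estimator between two sets of allele frequencies.

    With allele counts *n1*, *n2* the numerator subtracts the sampling
    variance of each frequency estimate; without counts the frequencies
    are treated as population values. Uses the ratio-of-means form.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2
    if n1 is not None:
        num = num - p1 * (1 - p1) / (np.asarray(n1) - 1)
    if n2 is not None:
        num = num - p2 * (1 - p2) / (np.asarray(n2) - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = np.isfinite(num) & np.isfinite(den) & (den > 0)
    return float(num[ok].mean() / den[ok].mean())
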