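"""Formal f-statistic tests for population mixture and ancestry proportions.

Three estimators built from per-SNP products of allele-frequency
differences, each with a block-jackknife standard error:

* **4 Population Test** (f4). If populations A,B form a clade relative to
  C,D, the drifts ``p_A - p_B`` and ``p_C - p_D`` accumulated on disjoint
  branches and the mean per-SNP product is zero. A jackknife Z-score with
  |Z| > 3 rejects the tree, indicating gene flow.
* **3 Population Test** (f3). For a target X and references A,B, the mean
  of ``(p_X - p_A)(p_X - p_B)`` is positive whenever X is a simple
  (unadmixed) descendant; a significantly negative value (Z < -3) proves
  X is a mixture of populations related to A and B. The raw product is
  inflated by the sampling variance of the X frequency estimate, so
  ``p_X(1-p_X)/(n_X - 1)`` is subtracted per SNP by default.
* **f4-ratio ancestry estimation**. The ratio of two f4 sums,
  ``sum (p_O1-p_O2)(p_X-p_R2) / sum (p_O1-p_O2)(p_R1-p_R2)``, isolates
  the proportion of ancestry X derives from the side of reference R1,
  without requiring data from the true ancestral populations.

Each test is exposed as a model object whose ``fit()`` returns a results
object carrying the estimate, jackknife SE, Z-score and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import FreqTable, SnpTable
from .jackknife import block_jackknife, block_partition, weighted_jackknife

__all__ = [
    "FourPopulationTest",
    "ThreePopulationTest",
    "F4Ratio",
    "FTestResults",
    "AncestryResults",
    "four_pop_test",
    "three_pop_test",
    "f4_ratio_ancestry",
]


@dataclass
class FTestResults:
    """Outcome of a 4- or 3-population test."""

    test: str
    labels: tuple
    statistic: float
    se: float
    z: float
    n_snps: int
    n_blocks: int
    normalized: float | None = None

    @property
    def significant(self) -> bool:
        """|Z| > 3, the conventional threshold for rejecting the tree."""
        return abs(self.z) > 3.0

    def summary(self) -> str:
        lines = [
            f"{self.test}  {' , '.join(self.labels)}",
            f"  statistic  {self.statistic: .6g}",
            f"  jackknife SE  {self.se:.6g}",
            f"  Z-score  {self.z: .3f}" + ("  *" if self.significant else ""),
            f"  SNPs {self.n_snps}   blocks {self.n_blocks}",
        ]
        if self.normalized is not None:
            lines.insert(2, f"  normalized corr  {self.normalized: .6g}")
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<{self.test}: stat={self.statistic:.4g} Z={self.z:.2f} "
            f"n_snps={self.n_snps}>"
        )


@dataclass
class AncestryResults:
    """f4-ratio ancestry proportion with jackknife uncertainty."""

    target: str
    references: tuple
    proportion: float
    se: float
    n_snps: int
    n_blocks: int

    def summary(self) -> str:
        o1, o2, r1, r2 = self.references
        return "\n".join(
            [
                f"f4-ratio ancestry of {self.target}",
                f"  references  ({o1} - {o2}) x ({r1} - {r2})",
                f"  proportion ({r1}-side)  {self.proportion:.4f} "
                f"({100 * self.proportion:.2f}%)",
                f"  jackknife SE  {self.se:.4f}",
                f"  SNPs {self.n_snps}   blocks {self.n_blocks}",
            ]
        )

    def __repr__(self):
        return (
            f"<AncestryResults {self.target}: {100 * self.proportion:.2f}% "
            f"+/- {100 * self.se:.2f}%>"
        )


def _resolve_blocks(freqs, snps, block_ids, block_size_cm):
    if block_ids is not None:
        return np.asarray(block_ids)
    if snps is None:
        raise ValueError("provide either block_ids or a SnpTable to build blocks")
    return block_partition(snps, block_size_cm)


def _filter_mask(freqs: FreqTable, labels) -> np.ndarray:
    """Retain SNPs with defined frequencies that are not monomorphic
    across every population in the test."""
    mask = freqs.defined_mask(labels)
    p = freqs.p[list(labels)].to_numpy()
    with np.errstate(invalid="ignore"):
        mono = (np.nanmax(p, axis=1) == 0) | (np.nanmin(p, axis=1) == 1)
    return mask & ~mono


class FourPopulationTest:
    """Test whether ((A,B),(C,D)) is a valid unrooted tree.

    Parameters
    ----------
    freqs : FreqTable
    a, b, c, d : population labels
    snps : SnpTable, optional
        Used to build contiguous jackknife blocks (default 5 cM).
    block_ids : array, optional
        Pre-computed block assignment per SNP row, overriding *snps*.
    """

    def __init__(self, freqs, a, b, c, d, snps=None, block_ids=None, block_size_cm=5.0):
        if len({a, b, c, d}) != 4:
            raise ValueError("the four population labels must be distinct")
        self.freqs = freqs
        self.labels = (a, b, c, d)
        self.block_ids = _resolve_blocks(freqs, snps, block_ids, block_size_cm)

    def fit(self) -> FTestResults:
        a, b, c, d = self.labels
        mask = _filter_mask(self.freqs, self.labels)
        if mask.sum() == 0:
            raise ValueError("no SNPs retained after filtering")
        da = self.freqs.freq(a)[mask] - self.freqs.freq(b)[mask]
        dc = self.freqs.freq(c)[mask] - self.freqs.freq(d)[mask]
        values = da * dc
        blocks = self.block_ids[mask]
        if np.unique(blocks).size < 2:
            raise ValueError("fewer than 2 jackknife blocks after filtering")
        stat, se = block_jackknife(values, blocks)
        z = stat / se if se > 0 else 0.0
        denom = np.sqrt((da**2).sum() * (dc**2).sum())
        normalized = float(values.sum() / denom) if denom > 0 else 0.0
        return FTestResults(
            test="4 Population Test",
            labels=self.labels,
            statistic=stat,
            se=se,
            z=z,
            n_snps=int(mask.sum()),
            n_blocks=int(np.unique(blocks).size),
            normalized=normalized,
        )


class ThreePopulationTest:
    """Test whether X descends from a mixture of populations related to A and B.

    The per-SNP statistic is ``(p_X - p_A)(p_X - p_B)`` minus, by default,
    the finite-sample correction ``p_X(1-p_X)/(n_X - 1)`` that removes the
    positive bias contributed by sampling variance of the X frequency.
    """

    def __init__(
        self,
        freqs,
        x,
        a,
        b,
        snps=None,
        block_ids=None,
        block_size_cm=5.0,
        sample_correction=True,
    ):
        if x == a or x == b:
            raise ValueError("target X must differ from both reference labels")
        self.freqs = freqs
        self.labels = (x, a, b)
        self.sample_correction = sample_correction
        self.block_ids = _resolve_blocks(freqs, snps, block_ids, block_size_cm)

    def fit(self) -> FTestResults:
        x, a, b = self.labels
        mask = _filter_mask(self.freqs, self.labels)
        n_x = self.freqs.counts(x)
        if self.sample_correction:
            mask = mask & (n_x >= 4)
        if mask.sum() == 0:
            raise ValueError("no SNPs retained after filtering")
        px = self.freqs.freq(x)[mask]
        values = (px - self.freqs.freq(a)[mask]) * (px - self.freqs.freq(b)[mask])
        if self.sample_correction:
            values = values - px * (1.0 - px) / (n_x[mask] - 1.0)
        blocks = self.block_ids[mask]
        if np.unique(blocks).size < 2:
            raise ValueError("fewer than 2 jackknife blocks after filtering")
        stat, se = block_jackknife(values, blocks)
        z = stat / se if se > 0 else 0.0
        return FTestResults(
            test="3 Population Test",
            labels=self.labels,
            statistic=stat,
            se=se,
            z=z,
            n_snps=int(mask.sum()),
            n_blocks=int(np.unique(blocks).size),
        )


class F4Ratio:
    """Ancestry proportion of *target* as a ratio of two f4 sums.

    With outgroups O1, O2 and references R1 (same side as the ancestry
    being measured) and R2 (the other side), the estimate is::

        sum (p_O1 - p_O2)(p_X  - p_R2)
        ------------------------------
        sum (p_O1 - p_O2)(p_R1 - p_R2)

    both sums over the same retained SNPs. The jackknife is carried out on
    the ratio itself, leaving one block of SNPs out of both sums at a time.
    """

    def __init__(
        self,
        freqs,
        outgroup1,
        outgroup2,
        ref1,
        ref2,
        target,
        snps=None,
        block_ids=None,
        block_size_cm=5.0,
    ):
        labels = (outgroup1, outgroup2, ref1, ref2, target)
        if len(set(labels)) != 5:
            raise ValueError("the five population labels must be distinct")
        self.freqs = freqs
        self.references = (outgroup1, outgroup2, ref1, ref2)
        self.target = target
        self.block_ids = _resolve_blocks(freqs, snps, block_ids, block_size_cm)

    def fit(self) -> AncestryResults:
        o1, o2, r1, r2 = self.references
        labels = (*self.references, self.target)
        mask = _filter_mask(self.freqs, labels)
        if mask.sum() == 0:
            raise ValueError("no SNPs retained after filtering")
        dout = self.freqs.freq(o1)[mask] - self.freqs.freq(o2)[mask]
        num = dout * (self.freqs.freq(self.target)[mask] - self.freqs.freq(r2)[mask])
        den = dout * (self.freqs.freq(r1)[mask] - self.freqs.freq(r2)[mask])
        blocks = self.block_ids[mask]
        uniq, inv = np.unique(blocks, return_inverse=True)
        if uniq.size < 2:
            raise ValueError("fewer than 2 jackknife blocks after filtering")
        num_sums = np.bincount(inv, weights=num)
        den_sums = np.bincount(inv, weights=den)
        weights = np.bincount(inv).astype(float)
        den_total = den_sums.sum()
        # informative-denominator guard: the f4 denominator must differ from
        # zero by more than its own jackknife noise
        _, den_se = block_jackknife(den, blocks)
        if abs(den_total / den.size) <= 3 * den_se or den_total == 0:
            raise ValueError(
                "uninformative reference configuration: f4 denominator is "
                "within jackknife noise of zero"
            )
        full = num_sums.sum() / den_total
        loo = (num_sums.sum() - num_sums) / (den_total - den_sums)
        est, se = weighted_jackknife(full, loo, weights)
        return AncestryResults(
            target=self.target,
            references=self.references,
            proportion=est,
            se=se,
            n_snps=int(mask.sum()),
            n_blocks=int(uniq.size),
        )


def four_pop_test(freqs, a, b, c, d, **kwargs) -> FTestResults:
    """Functional shorthand for ``FourPopulationTest(...).fit()``."""
    return FourPopulationTest(freqs, a, b, c, d, **kwargs).fit()


def three_pop_test(freqs, x, a, b, **kwargs) -> FTestResults:
    """Functional shorthand for ``ThreePopulationTest(...).fit()``."""
    return ThreePopulationTest(freqs, x, a, b, **kwargs).fit()


def f4_ratio_ancestry(
    freqs, outgroup1, outgroup2, ref1, ref2, target, **kwargs
) -> AncestryResults:
    """Functional shorthand for ``F4Ratio(...).fit()``."""
    return F4Ratio(freqs, outgroup1, outgroup2, ref1, ref2, target, **kwargs).fit()
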