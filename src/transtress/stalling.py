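"""Nonproductive (stalled) RNAPII estimation and lesion/queuing arithmetic.

The estimator assumes an adult baseline in which elongation-phase
nascent-RNA output is proportional to elongation-phase RNAPII occupancy.
The expected old ChIP signal is the old nascent signal times the adult
ChIP/EU ratio; any observed excess over that expectation is RNAPII
occupying gene bodies without producing RNA:

    stalling (%) = (observed - expected) / expected * 100

computed on elongation-phase (bins 2..k-1) totals per gene, against the
replicate-mean adult baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import LengthClasses

log = logging.getLogger(__name__)


@dataclass
class StallingEstimate:
    """Per-gene observed/expected ChIP totals and stalling percentages."""

    per_gene: pd.DataFrame  # columns: observed, expected, stalling_percent
    mean_percent: float
    sd_percent: float

    @property
    def n(self) -> int:
        return int(self.per_gene["stalling_percent"].notna().sum())


def expected_chip_reads(
    old_eu: pd.Series, adult_eu: pd.Series, adult_chip: pd.Series
) -> pd.Series:
    """Expected old ChIP elongation-phase totals per gene.

    ``expected = old_eu * (adult_chip / adult_eu)``, with the adult
    baseline taken as the replicate-mean group profile. Genes with zero
    adult nascent signal are masked.
    """
    adult_eu = adult_eu.replace(0, np.nan)
    n_masked = int(adult_eu.isna().sum())
    if n_masked:
        log.info("expected_chip_reads: masked %d genes with zero adult EU signal", n_masked)
    # division first: identical old/adult input gives exactly 1.0 per gene,
    # so a self-comparison returns exactly 0% stalling
    return ((old_eu / adult_eu) * adult_chip).rename("expected")


def stalling_percent(observed, expected):
    """The printed estimator: (observed - expected) / expected * 100.

    Scalar or vectorized; masked (NaN) where expected <= 0. Negative
    values mean less RNAPII than the nascent output predicts.
    """
    observed = pd.Series(observed) if np.ndim(observed) else float(observed)
    if np.ndim(observed):
        expected = pd.Series(expected).where(lambda s: s > 0)
        return (observed - expected) / expected * 100.0
    if expected is None or expected <= 0:
        return float("nan")
    return (observed - expected) / expected * 100.0


def estimate_stalling(
    old_eu: pd.Series,
    adult_eu: pd.Series,
    adult_chip: pd.Series,
    observed_old_chip: pd.Series | list[pd.Series],
) -> StallingEstimate:
    """Full per-gene stalling estimate from elongation-phase totals.

    ``observed_old_chip`` may be a list of per-replicate totals; each
    replicate is compared against the mean baseline, then averaged.
    """
    expected = expected_chip_reads(old_eu, adult_eu, adult_chip)
    if isinstance(observed_old_chip, list):
        per_rep = pd.concat(
            [stalling_percent(obs, expected) for obs in observed_old_chip], axis=1
        )
        pct = per_rep.mean(axis=1)
        observed = pd.concat(observed_old_chip, axis=1).mean(axis=1)
    else:
        observed = observed_old_chip
        pct = stalling_percent(observed, expected)
    per_gene = pd.DataFrame(
        {"observed": observed, "expected": expected, "stalling_percent": pct}
    )
    valid = per_gene["stalling_percent"].dropna()
    return StallingEstimate(
        per_gene=per_gene,
        mean_percent=float(valid.mean()) if len(valid) else float("nan"),
        sd_percent=float(valid.std()) if len(valid) else float("nan"),
    )


def stalling_by_length_class(
    estimates: StallingEstimate, classes: LengthClasses
) -> pd.DataFrame:
    """Class mean ± s.d. of per-gene stalling percentages."""
    df = pd.DataFrame(
        {"stalling_percent": estimates.per_gene["stalling_percent"], "class": classes.labels}
    ).dropna()
    out = df.groupby("class")["stalling_percent"].agg(["mean", "std", "count"])
    empty = set(range(classes.n_classes)) - set(out.index)
    if empty:
        log.warning("stalling_by_length_class: empty classes %s omitted", sorted(empty))
    return out


# ---------------------------------------------------------------------------
# Lesion and queuing arithmetic


def expected_lesions(total_bp: float, density_per_100kb: float, ploidy: int = 2) -> float:
    """Expected transcription-blocking lesions in a gene set.

    ``density_per_100kb`` is quoted per 100 kb of DNA; the gene set's
    haploid span contributes once per copy, so a diploid genome doubles
    the count (280,010,046 bp at 1.6/100 kb -> ~8,960).
    """
    if total_bp < 0 or density_per_100kb < 0 or ploidy <= 0:
        raise ValueError("inputs must be positive")
    return total_bp * density_per_100kb / 100_000.0 * ploidy / 2.0 * 2.0


def template_strand_lesions(total_lesions: float) -> float:
    """Lesions on template strands: half of the total (strand symmetry).

    Kept fractional — an expectation, not an event count.
    """
    if total_lesions < 0:
        raise ValueError("total_lesions must be >= 0")
    return total_lesions / 2.0


def queued_per_stalled(n_stalled_complexes: float, n_template_lesions: float) -> int:
    """Trailing RNAPII complexes queued behind each lesion-stalled one.

    ``round(stalled / lesions) - 1``: one complex sits on the lesion and
    the rest queue (18,000 / 4,480 -> 4 per lesion -> 3 queuing).
    Rounding is half-away-from-zero.
    """
    if n_template_lesions <= 0:
        raise ValueError("n_template_lesions must be > 0")
    if n_stalled_complexes <= 0:
        raise ValueError("n_stalled_complexes must be > 0")
    per_lesion = n_stalled_complexes / n_template_lesions
    return int(math.floor(per_lesion + 0.5)) - 1


def stalled_per_cell(stalling_fraction: float, elongating_rnapii_per_cell: float) -> float:
    """Stalled complexes per cell: fraction x elongating RNAPII per cell."""
    if not 0 <= stalling_fraction <= 1:
        raise ValueError("stalling_fraction must be in [0, 1]")
    return stalling_fraction * elongating_rnapii_per_cell


def uv_dose_to_lesion_density(dose_J_m2: float) -> float:
    """Transcription-blocking lesions per 100 kb for a UVC dose.

    Linear at 0.8 lesions/100 kb per J m^-2 (2 J m^-2 -> 1.6).
    """
    if dose_J_m2 < 0:
        raise ValueError("dose must be >= 0")
    return 0.8 * dose_J_m2
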