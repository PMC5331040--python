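"""Two-pool mass-balance mixing: per-sample recent-root C fractions.

The core statistic is the C-mass fraction of recent crop root biomass in a
sample,

    f = (delta_s - delta_EOM) / (delta_RB - delta_EOM),

where delta_s is the sample's delta13C and delta_RB, delta_EOM are the two
source signatures. f and the implied EOM-C fraction sum to 1 exactly. Raw
fractions may leave [0, 1] through measurement noise or endmember error;
they are clamped with an audit flag and all group statistics downstream use
the clamped scale. Conversion to biomass fractions assumes equal C
concentration across pools unless per-pool concentrations are supplied to
the size-class pooling step.

Uncertainty is attached two ways: a first-order (delta-method) analytic SE
over the three independent variance sources (sample measurement, root
endmember, EOM endmember), and a Monte-Carlo CI from Gaussian perturbation
of all three, clamped per draw.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .endmembers import EndmemberPair
from .study_data import (
    DegenerateEndmemberError,
    IsotopeSample,
    RootmixError,
    SampleTable,
    WeightingError,
)

log = logging.getLogger("rootmix")

#: Instrument SD of a single delta13C measurement (per mil): the stated
#: analytical precision of the IRMS working standard.
DEFAULT_SIGMA_S = 0.2
DEFAULT_DRAWS = 10_000
#: Monte-Carlo draws whose perturbed endmember separation falls below this
#: (per mil) are rejected and redrawn: the mixing ratio is unstable there.
MC_MIN_SEPARATION = 0.1

FLAG_IN_RANGE = "in_range"
FLAG_CLAMPED_HIGH = "clamped_high"
FLAG_CLAMPED_LOW = "clamped_low"


@dataclass(frozen=True)
class MixingResult:
    """Per-sample partitioning result.

    ``raw_fraction`` is the unclamped mass-balance value kept for audit;
    ``fraction`` is clamped to [0, 1] and is what all group statistics use.
    CI bounds are reported on the clamped scale; they are NaN when the
    Monte-Carlo stage was not run.
    """

    sample_id: str
    raw_fraction: float
    fraction: float
    se_analytic: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    flag: str = FLAG_IN_RANGE


def _clamp_flag(raw: float) -> tuple[float, str]:
    if raw > 1.0:
        return 1.0, FLAG_CLAMPED_HIGH
    if raw < 0.0:
        return 0.0, FLAG_CLAMPED_LOW
    return raw, FLAG_IN_RANGE


def raw_fractions(delta_s, pair: EndmemberPair) -> np.ndarray:
    """Vectorized unclamped mixing fractions for an array of delta13C."""
    delta_s = np.asarray(delta_s, dtype=float)
    return (delta_s - pair.eom.mean) / pair.separation


def mixing_fraction(delta_s: float, pair: EndmemberPair,
                    sample_id: str = "") -> MixingResult:
    """Point-estimate mixing result for one sample (no Monte-Carlo CI)."""
    raw = float(raw_fractions(delta_s, pair))
    fraction, flag = _clamp_flag(raw)
    return MixingResult(sample_id, raw, fraction, math.nan, flag=flag)


def analytic_se(delta_s: float, pair: EndmemberPair,
                sigma_s: float = DEFAULT_SIGMA_S) -> float:
    """First-order SE of the raw fraction from the three variance sources.

    Partial derivatives of f = (d_s - d_EOM)/(d_RB - d_EOM) give

        SE^2 = (s_s/D)^2 + (s_RB (d_s - d_EOM)/D^2)^2
             + (s_EOM (d_s - d_RB)/D^2)^2,   D = d_RB - d_EOM,

    evaluated at the unclamped point.
    """
    if sigma_s < 0 or pair.root.sd < 0 or pair.eom.sd < 0:
        raise ValueError("all SDs must be >= 0")
    d = pair.separation
    t_s = sigma_s / d
    t_rb = pair.root.sd * (delta_s - pair.eom.mean) / d ** 2
    t_eom = pair.eom.sd * (delta_s - pair.root.mean) / d ** 2
    return math.sqrt(t_s ** 2 + t_rb ** 2 + t_eom ** 2)


def mc_uncertainty(delta_s: float, pair: EndmemberPair,
                   sigma_s: float = DEFAULT_SIGMA_S,
                   draws: int = DEFAULT_DRAWS, seed: int = 0
                   ) -> tuple[float, float, float]:
    """Monte-Carlo (ci_low, ci_high, se) of the clamped fraction.

    Draws Gaussian perturbations of the sample value and both endmember
    means with their SDs, recomputes and clamps the fraction per draw, and
    returns the 2.5/97.5 percentile interval and the SD of the clamped
    draws. Draws whose perturbed separation falls below
    :data:`MC_MIN_SEPARATION` are rejected and redrawn (count logged).
    Deterministic given *seed*.
    """
    if draws < 1000:
        raise ValueError(f"need draws >= 1000, got {draws}")
    rng = np.random.default_rng(seed)
    ds = rng.normal(delta_s, sigma_s, draws)
    rb = rng.normal(pair.root.mean, pair.root.sd, draws)
    eom = rng.normal(pair.eom.mean, pair.eom.sd, draws)
    rejected = 0
    bad = np.abs(rb - eom) < MC_MIN_SEPARATION
    while bad.any():
        k = int(bad.sum())
        rejected += k
        rb[bad] = rng.normal(pair.root.mean, pair.root.sd, k)
        eom[bad] = rng.normal(pair.eom.mean, pair.eom.sd, k)
        bad = np.abs(rb - eom) < MC_MIN_SEPARATION
    if rejected:
        log.info("mc_uncertainty: redrew %d near-degenerate draw(s)",
                 rejected)
    f = np.clip((ds - eom) / (rb - eom), 0.0, 1.0)
    lo, hi = np.percentile(f, [2.5, 97.5])
    return float(lo), float(hi), float(f.std())


def pool_size_classes(f_coarse: float, f_fine: float,
                      mass_coarse: float, mass_fine: float,
                      c_conc_coarse: float | None = None,
                      c_conc_fine: float | None = None) -> float:
    """Mass-weighted average of coarse and fine clamped fractions.

    Weights are dry masses, refined to C masses (dry mass x C concentration)
    when both concentrations are supplied. The pooled value always lies
    between the two inputs.
    """
    if mass_coarse < 0 or mass_fine < 0:
        raise WeightingError("masses must be >= 0")
    w_c, w_f = mass_coarse, mass_fine
    if c_conc_coarse is not None and c_conc_fine is not None:
        w_c *= c_conc_coarse
        w_f *= c_conc_fine
    total = w_c + w_f
    if total <= 0:
        raise WeightingError("pooling weights are all zero")
    return (w_c * f_coarse + w_f * f_fine) / total


def run_mixing(table: SampleTable, pair: EndmemberPair,
               sigma_s: float = DEFAULT_SIGMA_S,
               draws: int = DEFAULT_DRAWS, seed: int = 0
               ) -> list[MixingResult]:
    """Apply the mixing model to every sample and synthesize pooled records.

    Returns one :class:`MixingResult` per measured sample, followed by one
    synthesized Puerckhauer "pooled" result per plot x depth that has both a
    coarse and a fine result with dry masses (mass-weighted average; skipped
    with a warning otherwise). Set ``draws=0`` to skip the per-sample
    Monte-Carlo stage and report the analytic SE only.
    """
    if pair.separation < pair.min_separation:
        raise DegenerateEndmemberError("endmember separation too small")
    results: list[MixingResult] = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(table.records)) % (2 ** 31)
    by_cell: dict[tuple, dict[str, tuple[IsotopeSample, MixingResult]]] = {}
    for rec, sub_seed in zip(table.records, child_seeds):
        raw = float(raw_fractions(rec.delta13c, pair))
        fraction, flag = _clamp_flag(raw)
        se = analytic_se(rec.delta13c, pair, sigma_s)
        if draws:
            lo, hi, _ = mc_uncertainty(rec.delta13c, pair, sigma_s,
                                       draws, int(sub_seed))
        else:
            lo = hi = math.nan
        res = MixingResult(rec.sample_id, raw, fraction, se, lo, hi, flag)
        results.append(res)
        if rec.method == "puerckhauer" and rec.size_class in ("coarse",
                                                              "fine"):
            cell = by_cell.setdefault((rec.plot_id, rec.depth), {})
            cell[rec.size_class] = (rec, res)
    for (plot, depth), cell in sorted(by_cell.items()):
        if "coarse" not in cell or "fine" not in cell:
            continue
        rec_c, res_c = cell["coarse"]
        rec_f, res_f = cell["fine"]
        if rec_c.dry_mass is None or rec_f.dry_mass is None:
            log.warning("no pooled record for %s/%s: dry mass missing",
                        plot, depth)
            continue
        pooled = pool_size_classes(res_c.fraction, res_f.fraction,
                                   rec_c.dry_mass, rec_f.dry_mass,
                                   rec_c.c_concentration,
                                   rec_f.c_concentration)
        raw_pooled = pool_size_classes(res_c.raw_fraction, res_f.raw_fraction,
                                       rec_c.dry_mass, rec_f.dry_mass,
                                       rec_c.c_concentration,
                                       rec_f.c_concentration)
        w_c, w_f = rec_c.dry_mass, rec_f.dry_mass
        if rec_c.c_concentration is not None and \
                rec_f.c_concentration is not None:
            w_c *= rec_c.c_concentration
            w_f *= rec_f.c_concentration
        tot = w_c + w_f
        se_pooled = math.sqrt((w_c * res_c.se_analytic) ** 2 +
                              (w_f * res_f.se_analytic) ** 2) / tot
        if draws:
            lo = (w_c * res_c.ci_low + w_f * res_f.ci_low) / tot
            hi = (w_c * res_c.ci_high + w_f * res_f.ci_high) / tot
        else:
            lo = hi = math.nan
        frac, flag = _clamp_flag(pooled)
        results.append(MixingResult(
            f"{plot}-{depth}-puerckhauer-row-pooled", raw_pooled, frac,
            se_pooled, lo, hi, flag))
    return results


def augment_with_pooled(table: SampleTable, results: list[MixingResult],
                        pair: EndmemberPair) -> SampleTable:
    """Append derived Puerckhauer pooled records to *table*.

    The derived record's delta13C is the signature implied by its pooled
    fraction (EOM mean + fraction x separation), so the augmented table
    stays schema-valid and the exclusion subset can be built from it.
    """
    by_id = {r.sample_id for r in table.records}
    by_cell = {}
    for rec in table.records:
        if rec.method == "puerckhauer" and rec.size_class == "coarse":
            by_cell[(rec.plot_id, rec.depth)] = rec
    extra: list[IsotopeSample] = []
    for res in results:
        if res.sample_id in by_id or not res.sample_id.endswith("-pooled"):
            continue
        plot, depth = res.sample_id.split("-")[0], res.sample_id.split("-")[1]
        proto = by_cell.get((plot, depth))
        if proto is None:
            continue
        extra.append(replace(
            proto, sample_id=res.sample_id, size_class="pooled",
            delta13c=pair.eom.mean + res.raw_fraction * pair.separation,
            dry_mass=None, c_concentration=None, derived=True))
    return SampleTable(table.records + extra, table.provenance)
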