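"""Synthetic study generator emulating the sampling design of the field trial.

The generator produces studies with the statistical structure the pipeline
assumes, so every stage can be exercised and checked against a known latent
truth without any external data:

* a complete 3 treatment x 4 block x 3 depth factorial over 12 plots, with
  the two coring streams (Humax: 2 positions, pooled size, EOM excluded;
  Puerckhauer: in-row, coarse + fine, no exclusion) — 144 planned records;
* latent true recent-root C fractions drawn logit-normally, with additive
  factor effects on the logit scale (keeps fractions strictly inside (0,1)
  and yields the long observed tail, 5-100%);
* a sub-population of nearly pure coarse samples: cores that happened to
  catch only recent crop roots. The upper-quantile root-endmember rule is
  consistent precisely when at least 1-q of coarse samples are pure, so the
  generator reproduces that feature of real samples (the empirical CDF of
  coarse values plateaus at the pure-root signature);
* per-sample realized endmember signatures (biological heterogeneity) plus
  instrument noise on the measured delta13C;
* uniformly random missingness (the realized study drops 5 of 144 records).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .study_data import (
    BLOCKS,
    DEPTHS,
    IsotopeSample,
    RootmixError,
    SampleTable,
    TREATMENTS,
)

log = logging.getLogger("rootmix")


class ScenarioError(RootmixError):
    """Invalid generative scenario."""


def _baseline_effects() -> dict:
    # logit-scale offsets calibrated so cell means track the observed group
    # means (treatment 55/59/66%, depth 52/60/68%, position 73/52%, size
    # class 73/42%, exclusion 53/74%)
    return {
        "treatment": {"BIOORG1": -0.22, "BIOORG2": -0.04, "CONFYM2": 0.26},
        "depth": {"D1": -0.33, "D2": 0.0, "D3": 0.34},
        "position": {"row": 0.46, "inter_row": -0.46},
        "size_class": {"pooled": 0.0, "coarse": 0.66, "fine": -0.66},
        "exclusion": {"yes": 0.47, "no": -0.47},
    }


@dataclass
class Scenario:
    """Generative truth for a synthetic study.

    Defaults reproduce the study conditions of the emulated trial:
    endmembers -13.3 +/- 0.5 (root) and -29.3 +/- 0.3 (EOM) per mil,
    instrument SD 0.2 per mil, 5 of 144 observations missing. Effects are
    additive offsets on the logit of the true fraction.
    """

    root_endmember: tuple[float, float] = (-13.3, 0.5)
    eom_endmember: tuple[float, float] = (-29.3, 0.3)
    sigma_instrument: float = 0.2
    baseline_fraction: float = 0.55
    effects: dict = field(default_factory=_baseline_effects)
    #: optional extra logit offset applied to excluded samples per treatment
    #: (mimics exclusion helping some treatments more than others)
    interaction_treatment_exclusion: dict = field(default_factory=dict)
    dispersion_logit: float = 0.9
    n_missing: int = 5
    mass_ratio_fine_to_coarse: float = 1.5
    #: probability that a coarse sample contains only recent crop roots
    coarse_pure_prob: float = 0.25
    #: logit-scale location/spread of the pure sub-population (~0.99 fraction)
    pure_logit_mean: float = 4.6
    pure_logit_sd: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.baseline_fraction < 1.0):
            raise ScenarioError("baseline_fraction must be in (0, 1)")
        for name in ("sigma_instrument", "dispersion_logit",
                     "pure_logit_sd"):
            if getattr(self, name) < 0:
                raise ScenarioError(f"{name} must be >= 0")
        if self.root_endmember[1] < 0 or self.eom_endmember[1] < 0:
            raise ScenarioError("endmember SDs must be >= 0")
        if not (self.root_endmember[0] > self.eom_endmember[0]):
            raise ScenarioError("root endmember must exceed EOM endmember")
        if not (0 <= self.n_missing < 144):
            raise ScenarioError("n_missing must be in [0, design size)")
        if not (0.0 <= self.coarse_pure_prob <= 1.0):
            raise ScenarioError("coarse_pure_prob must be a probability")
        if self.mass_ratio_fine_to_coarse <= 0:
            raise ScenarioError("mass_ratio_fine_to_coarse must be > 0")
        for factor, offsets in self.effects.items():
            for level, off in offsets.items():
                if not np.isfinite(off):
                    raise ScenarioError(
                        f"effect {factor}[{level}] not finite")

    @classmethod
    def null(cls, **kw) -> "Scenario":
        """A scenario with no true effects (for calibration studies)."""
        eff = {f: {k: 0.0 for k in v}
               for f, v in _baseline_effects().items()}
        kw.setdefault("effects", eff)
        kw.setdefault("coarse_pure_prob", 0.0)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ScenarioError(f"unknown scenario key(s): {sorted(unknown)}")
        for key in ("root_endmember", "eom_endmember"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


def build_design() -> pd.DataFrame:
    """The complete planned design: 144 rows over 12 plots x 3 depths.

    Per plot x depth: two Humax records (row, inter_row; pooled; excluded)
    and two Puerckhauer records (row; coarse, fine; not excluded).
    """
    rows = []
    plot_num = 0
    for block in BLOCKS:
        for treatment in TREATMENTS:
            plot_num += 1
            plot = f"P{plot_num:02d}"
            for depth in DEPTHS:
                for position in ("row", "inter_row"):
                    rows.append((plot, treatment, block, depth, position,
                                 "humax", "pooled", True))
                for size_class in ("coarse", "fine"):
                    rows.append((plot, treatment, block, depth, "row",
                                 "puerckhauer", size_class, False))
    df = pd.DataFrame(rows, columns=[
        "plot_id", "treatment", "block", "depth", "position", "method",
        "size_class", "eom_excluded"])
    df.insert(0, "sample_id", df["plot_id"] + "-" + df["depth"] + "-" +
              df["method"] + "-" + df["position"] + "-" + df["size_class"])
    return df


# ---------------------------------------------------------------------------
# Truth and measurements
# ---------------------------------------------------------------------------


def draw_true_fractions(design: pd.DataFrame, scenario: Scenario,
                        seed: int = 0) -> pd.DataFrame:
    """Draw latent true fractions for every design row (deterministic in seed).

    logit(f) = logit(baseline) + sum of applicable factor offsets
             + Normal(0, dispersion); coarse samples are replaced, with
    probability ``coarse_pure_prob``, by draws from the nearly pure
    sub-population.
    """
    rng = np.random.default_rng(seed)
    eff = scenario.effects
    lp = np.full(len(design), logit(scenario.baseline_fraction))
    lp += design["treatment"].map(eff.get("treatment", {})).fillna(0.0)
    lp += design["depth"].map(eff.get("depth", {})).fillna(0.0)
    lp += design["position"].map(eff.get("position", {})).fillna(0.0)
    lp += design["size_class"].map(eff.get("size_class", {})).fillna(0.0)
    excl = design["eom_excluded"].map(
        lambda b: eff.get("exclusion", {}).get("yes" if b else "no", 0.0))
    lp += excl
    if scenario.interaction_treatment_exclusion:
        extra = design["treatment"].map(
            scenario.interaction_treatment_exclusion).fillna(0.0)
        lp += np.where(design["eom_excluded"], extra, 0.0)
    lp = lp.to_numpy(dtype=float)
    lp += rng.normal(0.0, scenario.dispersion_logit, len(design))
    is_coarse = (design["size_class"] == "coarse").to_numpy()
    pure = is_coarse & (rng.random(len(design)) < scenario.coarse_pure_prob)
    if pure.any():
        lp[pure] = rng.normal(scenario.pure_logit_mean,
                              scenario.pure_logit_sd, int(pure.sum()))
    truth = design.copy()
    truth["true_fraction"] = expit(lp)
    if not ((truth["true_fraction"] > 0) & (truth["true_fraction"] < 1)).all():
        raise ScenarioError("implied true fractions leave (0, 1)")
    return truth


def synthesize_delta13c(truth: pd.DataFrame, scenario: Scenario,
                        seed: int = 0) -> SampleTable:
    """Realize measured delta13C values from latent truths.

    Each sample gets its own realized endmember signatures (biological
    heterogeneity of root and EOM material) plus instrument noise:

        delta = f * root_i + (1 - f) * eom_i + Normal(0, sigma_instrument).

    Dry masses implement the scenario's fine:coarse mass ratio for the
    Puerckhauer classes; C concentration is a typical constant for root
    material.
    """
    rng = np.random.default_rng(seed)
    n = len(truth)
    root_mu, root_sd = scenario.root_endmember
    eom_mu, eom_sd = scenario.eom_endmember
    realized_root = rng.normal(root_mu, root_sd, n)
    realized_eom = rng.normal(eom_mu, eom_sd, n)
    f = truth["true_fraction"].to_numpy()
    delta = (f * realized_root + (1 - f) * realized_eom
             + rng.normal(0.0, scenario.sigma_instrument, n))
    truth = truth.assign(realized_root_delta=realized_root,
                         realized_eom_delta=realized_eom)
    records = []
    for row, d in zip(truth.to_dict("records"), delta):
        if row["method"] == "puerckhauer":
            mass = 1.0 if row["size_class"] == "coarse" else \
                scenario.mass_ratio_fine_to_coarse
        else:
            mass = 1.0
        records.append(IsotopeSample(
            sample_id=row["sample_id"], plot_id=row["plot_id"],
            treatment=row["treatment"], block=int(row["block"]),
            depth=row["depth"], position=row["position"],
            method=row["method"], size_class=row["size_class"],
            eom_excluded=bool(row["eom_excluded"]),
            delta13c=float(np.clip(d, -40.0, 0.0)),
            dry_mass=mass, c_concentration=0.45))
    return SampleTable(records, provenance="synthetic")


def apply_missingness(table: SampleTable, n_missing: int, seed: int = 0
                      ) -> SampleTable:
    """Remove *n_missing* uniformly random records (deterministic in seed)."""
    if n_missing >= len(table):
        raise ScenarioError("n_missing must be smaller than the table")
    if n_missing == 0:
        return SampleTable(list(table.records), table.provenance)
    rng = np.random.default_rng(seed)
    drop = set(rng.choice(len(table), size=n_missing, replace=False))
    kept = [r for i, r in enumerate(table.records) if i not in drop]
    return SampleTable(kept, table.provenance)


def generate_reference_ley(scenario: Scenario, n: int = 12, seed: int = 0
                           ) -> pd.DataFrame:
    """Prior-year ley fine-root reference values ~ Normal(EOM endmember)."""
    if n < 2:
        raise ScenarioError("reference set needs n >= 2")
    rng = np.random.default_rng(seed)
    mu, sd = scenario.eom_endmember
    values = rng.normal(mu, sd, n)
    plots = [f"P{(i % 12) + 1:02d}" for i in range(n)]
    treatments = [TREATMENTS[(i % 12) % 3] for i in range(n)]
    return pd.DataFrame({
        "sample_id": [f"LEY-{i + 1:02d}" for i in range(n)],
        "plot_id": plots,
        "treatment": treatments,
        "delta13c": values,
    })


def generate_study(scenario: Scenario, seed: int = 0
                   ) -> tuple[SampleTable, pd.DataFrame, pd.DataFrame]:
    """Generate one complete synthetic study.

    Returns ``(samples, reference, truth)``: the realized sample table
    (after missingness), the ley reference table, and the latent truth for
    every planned record (before missingness), for recovery checks.
    """
    sub = np.random.SeedSequence(seed).generate_state(4) % (2 ** 31)
    design = build_design()
    truth = draw_true_fractions(design, scenario, seed=int(sub[0]))
    table = synthesize_delta13c(truth, scenario, seed=int(sub[1]))
    table = apply_missingness(table, scenario.n_missing, seed=int(sub[2]))
    reference = generate_reference_ley(scenario, seed=int(sub[3]))
    return table, reference, truth
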