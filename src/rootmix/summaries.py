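"""Factorial group summaries and design-respecting permutation tests.

The original analysis of this kind of split-plot field design uses linear
mixed models with Kenward-Roger F-tests. Here inference is by permutation
instead: the observed between-level mean square is compared with its
distribution under permutations that respect the experimental unit of each
factor —

* ``treatment`` is randomized to whole plots, so treatment labels are
  permuted across plots (optionally within blocks);
* ``depth`` varies within plots, so depth labels are permuted among the
  depth groups of each plot;
* ``position``, ``size_class`` and ``eom_excluded`` vary within a
  plot x depth cell, so their labels are permuted within cells.

Interactions are tested by the Freedman-Lane scheme: residuals from the
additive fit are permuted, the additive fit is added back, and the
interaction mean square of each reconstructed response is compared with the
observed one. Permutation p-values are exact up to Monte-Carlo error and
make no normality or variance-component assumptions; they will not
numerically match mixed-model p-values.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .study_data import DesignError, SpecificationError

log = logging.getLogger("rootmix")

DEFAULT_B = 9_999
#: Below this many distinct permutations, the null is enumerated exactly.
ENUMERATION_THRESHOLD = 20

FACTORS = ("treatment", "depth", "position", "size_class", "eom_excluded")
#: Analysis subset on which each factor contrast is defined.
SUBSET_FOR_EFFECT = {
    "treatment": "full",
    "depth": "full",
    "position": "positions",
    "size_class": "size_classes",
    "eom_excluded": "exclusion",
}


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SE (n) of fractions in one factorial cell."""

    factor_levels: dict
    mean: float
    se: float | None
    n: int


@dataclass(frozen=True)
class FactorTest:
    """Permutation test result for one main effect or interaction."""

    subset_name: str
    effect: str
    statistic: float
    p_perm: float
    B: int
    seed: int


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def summarize(frame: pd.DataFrame, factors: list[str],
              value: str = "fraction") -> list[GroupSummary]:
    """Per-cell mean, SE (sample SD / sqrt(n), n-1 denominator) and n.

    *frame* joins fractions to design factors (see
    :func:`results_frame`). Cells with a single value report no SE.
    """
    for f in factors:
        if f not in frame.columns:
            raise SpecificationError(f"unknown factor {f!r}")
    out: list[GroupSummary] = []
    for levels, grp in frame.groupby(factors, sort=True, observed=True):
        if not isinstance(levels, tuple):
            levels = (levels,)
        vals = grp[value].to_numpy(dtype=float)
        n = vals.size
        se = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else None
        out.append(GroupSummary(dict(zip(factors, levels)),
                                float(vals.mean()), se, int(n)))
    return out


def results_frame(table, results) -> pd.DataFrame:
    """Join mixing results to design factors by sample_id."""
    res = pd.DataFrame(
        [{"sample_id": r.sample_id, "raw_fraction": r.raw_fraction,
          "fraction": r.fraction, "se_analytic": r.se_analytic,
          "flag": r.flag} for r in results])
    design = table.to_frame().drop(
        columns=["delta13c", "dry_mass", "c_concentration"])
    return design.merge(res, on="sample_id", how="inner")


def subset_frame(frame: pd.DataFrame, name: str) -> pd.DataFrame:
    """Select the analysis subset *name* from a joined results frame."""
    measured = ~frame["derived"] if "derived" in frame.columns else \
        pd.Series(True, index=frame.index)
    if name == "full":
        return frame[measured]
    if name == "positions":
        return frame[measured & (frame["method"] == "humax")]
    if name == "size_classes":
        return frame[measured & (frame["method"] == "puerckhauer")
                     & frame["size_class"].isin(["coarse", "fine"])]
    if name == "exclusion":
        return frame[(frame["position"] == "row")
                     & (frame["size_class"] == "pooled")]
    raise SpecificationError(f"unknown subset {name!r}")


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------


def _between_ms(y: np.ndarray, codes: np.ndarray, k: int) -> float:
    counts = np.bincount(codes, minlength=k)
    sums = np.bincount(codes, weights=y, minlength=k)
    means = sums / counts
    return float((counts * (means - y.mean()) ** 2).sum() / (k - 1))


class _Scheme:
    """Label-permutation scheme respecting a factor's experimental unit."""

    def __init__(self, frame: pd.DataFrame, factor: str,
                 within_blocks: bool = False):
        self.labels = frame[factor].to_numpy()
        self.levels, self.codes = np.unique(self.labels, return_inverse=True)
        if self.levels.size < 2:
            raise DesignError(f"factor {factor!r} has fewer than 2 levels")
        self.factor = factor
        if factor == "treatment":
            plots = frame["plot_id"].to_numpy()
            self.units, self.unit_of_row = np.unique(plots,
                                                     return_inverse=True)
            # each plot carries one treatment label
            first = pd.DataFrame({"u": self.unit_of_row,
                                  "c": self.codes}).groupby("u")["c"].first()
            self.unit_codes = first.to_numpy()
            if within_blocks:
                blocks = frame.groupby("plot_id", sort=True)["block"].first()
                self.unit_groups = blocks.to_numpy()
            else:
                self.unit_groups = np.zeros(self.units.size, dtype=int)
        elif factor == "depth":
            # permute depth labels among the depth groups of each plot
            key = frame["plot_id"].astype(str) + "|" + frame[factor].astype(str)
            self.units, self.unit_of_row = np.unique(key.to_numpy(),
                                                     return_inverse=True)
            first = pd.DataFrame({"u": self.unit_of_row,
                                  "c": self.codes}).groupby("u")["c"].first()
            self.unit_codes = first.to_numpy()
            plot_of_unit = pd.DataFrame(
                {"u": self.unit_of_row,
                 "p": frame["plot_id"].to_numpy()}).groupby("u")["p"].first()
            _, self.unit_groups = np.unique(plot_of_unit.to_numpy(),
                                            return_inverse=True)
        else:
            # within plot x depth cell, permute labels among rows
            key = frame["plot_id"].astype(str) + "|" + frame["depth"].astype(str)
            _, cell = np.unique(key.to_numpy(), return_inverse=True)
            self.units = np.arange(len(frame))
            self.unit_of_row = self.units
            self.unit_codes = self.codes.copy()
            self.unit_groups = cell
        # unit indices per permutation group
        self.group_members = [np.flatnonzero(self.unit_groups == g)
                              for g in np.unique(self.unit_groups)]

    def n_distinct(self) -> float:
        total = 1.0
        for members in self.group_members:
            c = self.unit_codes[members]
            counts = np.bincount(c, minlength=self.levels.size)
            perms = math.factorial(len(members))
            for k in counts:
                perms //= math.factorial(int(k))
            total *= perms
            if total > 1e12:
                return total
        return total

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        codes = self.unit_codes.copy()
        for members in self.group_members:
            codes[members] = codes[rng.permutation(members)]
        return codes[self.unit_of_row]

    def enumerate_all(self):
        per_group = []
        for members in self.group_members:
            opts = [np.array(p) for p in sorted(set(
                itertools.permutations(self.unit_codes[members])))]
            per_group.append((members, opts))
        for combo in itertools.product(*(opts for _, opts in per_group)):
            codes = self.unit_codes.copy()
            for (members, _), perm in zip(per_group, combo):
                codes[members] = perm
            yield codes[self.unit_of_row]


def permutation_main_effect(frame: pd.DataFrame, factor: str,
                            B: int = DEFAULT_B, seed: int = 0,
                            within_blocks: bool = False,
                            value: str = "fraction",
                            subset_name: str = "") -> FactorTest:
    """Design-respecting permutation test of one main effect.

    The statistic is the between-level mean square of the fractions. With
    fewer than 20 distinct permutations the null is enumerated exactly
    (logged); otherwise *B* random permutations are drawn.
    """
    if factor not in frame.columns:
        raise SpecificationError(f"unknown factor {factor!r}")
    y = frame[value].to_numpy(dtype=float)
    scheme = _Scheme(frame, factor, within_blocks)
    k = scheme.levels.size
    observed = _between_ms(y, scheme.codes, k)
    n_distinct = scheme.n_distinct()
    tol = 1e-12 * max(observed, 1.0)
    if n_distinct < ENUMERATION_THRESHOLD:
        log.info("factor %r: only %d distinct permutations; enumerating",
                 factor, int(n_distinct))
        stats = [_between_ms(y, codes, k) for codes in scheme.enumerate_all()]
        hits = sum(s >= observed - tol for s in stats)
        p = hits / len(stats)
        B_used = len(stats)
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(B):
            if _between_ms(y, scheme.draw(rng), k) >= observed - tol:
                hits += 1
        p = (1 + hits) / (B + 1)
        B_used = B
    return FactorTest(subset_name or SUBSET_FOR_EFFECT.get(factor, ""),
                      factor, observed, p, B_used, seed)


def permutation_interaction(frame: pd.DataFrame, factor_a: str,
                            factor_b: str, B: int = DEFAULT_B,
                            seed: int = 0, value: str = "fraction",
                            subset_name: str = "") -> FactorTest:
    """Freedman-Lane residual-permutation test of an a x b interaction.

    The statistic is the interaction mean square, computed as the reduction
    in residual sum of squares from the additive to the full cell-means
    model, divided by (a-1)(b-1). Residuals from the additive fit are
    permuted freely, the additive fit is added back, and the statistic is
    recomputed per permutation.
    """
    for f in (factor_a, factor_b):
        if f not in frame.columns:
            raise SpecificationError(f"unknown factor {f!r}")
    y = frame[value].to_numpy(dtype=float)
    la, ca = np.unique(frame[factor_a].to_numpy(), return_inverse=True)
    lb, cb = np.unique(frame[factor_b].to_numpy(), return_inverse=True)
    if la.size < 2 or lb.size < 2:
        raise DesignError("interaction test needs >= 2 levels per factor")
    cells = np.unique(np.stack([ca, cb], axis=1), axis=0)
    if cells.shape[0] < la.size * lb.size:
        raise DesignError("interaction test needs all a x b cells non-empty")

    def dummies(codes: np.ndarray, k: int) -> np.ndarray:
        d = np.zeros((codes.size, k - 1))
        for j in range(1, k):
            d[codes == j, j - 1] = 1.0
        return d

    n = y.size
    x_add = np.column_stack([np.ones(n), dummies(ca, la.size),
                             dummies(cb, lb.size)])
    inter = dummies(ca, la.size)[:, :, None] * \
        dummies(cb, lb.size)[:, None, :]
    x_full = np.column_stack([x_add, inter.reshape(n, -1)])
    q_add, _ = np.linalg.qr(x_add)
    q_full, _ = np.linalg.qr(x_full)
    df_int = (la.size - 1) * (lb.size - 1)

    def int_ms(v: np.ndarray) -> float:
        tot = v @ v
        rss_add = tot - (q_add.T @ v) @ (q_add.T @ v)
        rss_full = tot - (q_full.T @ v) @ (q_full.T @ v)
        return float((rss_add - rss_full) / df_int)

    observed = int_ms(y)
    fitted = q_add @ (q_add.T @ y)
    resid = y - fitted
    rng = np.random.default_rng(seed)
    tol = 1e-12 * max(observed, 1.0)
    hits = 0
    for _ in range(B):
        y_star = fitted + resid[rng.permutation(n)]
        if int_ms(y_star) >= observed - tol:
            hits += 1
    p = (1 + hits) / (B + 1)
    return FactorTest(subset_name, f"{factor_a}:{factor_b}", observed, p,
                      B, seed)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def format_cell(mean: float, se: float | None, n: int) -> str:
    """Render one summary cell, e.g. ``0.44 ± 0.07 (16)``."""
    if se is None:
        return f"{mean:.2f} ({n})"
    return f"{mean:.2f} ± {se:.2f} ({n})"


def report_table2(frame: pd.DataFrame, value: str = "fraction") -> str:
    """Depth x treatment grid of "mean ± se (n)" strings.

    Treatments with no data are omitted with a warning; populated cells
    show the cell mean, its standard error and the cell count.
    """
    from .study_data import DEPTHS, DEPTH_RANGES_M, TREATMENTS

    present = [t for t in TREATMENTS if (frame["treatment"] == t).any()]
    for t in TREATMENTS:
        if t not in present:
            log.warning("treatment %r has no data; column omitted", t)
    cells = {(s.factor_levels["depth"], s.factor_levels["treatment"]):
             format_cell(s.mean, s.se, s.n)
             for s in summarize(frame, ["depth", "treatment"], value=value)}
    widths = {t: max(len(t), *(len(cells.get((d, t), "")) for d in DEPTHS))
              for t in present}
    label = "Depth [m]"
    lw = max(len(label), *(len(f"{a}-{b}") for a, b in
                           DEPTH_RANGES_M.values()))
    lines = [label.ljust(lw) + "  " +
             "  ".join(t.ljust(widths[t]) for t in present)]
    for d in DEPTHS:
        a, b = DEPTH_RANGES_M[d]
        row = f"{a:g}-{b:g}".ljust(lw)
        for t in present:
            row += "  " + cells.get((d, t), "-").ljust(widths[t])
        lines.append(row)
    return "\n".join(lines)
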