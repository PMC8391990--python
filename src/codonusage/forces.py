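"""Attribution of codon usage to mutation, selection and composition.

Three classical diagnostics are implemented:

* **Neutrality plot** — OLS regression of GC12 (mean G+C percent at
  codon positions 1 and 2) on GC3 across the genes of a panel. A slope
  near 1 means directional mutation pressure moves all positions
  together; a slope near 0 means selection holds the non-synonymous
  positions in place while GC3 drifts. 100·slope is reported as the
  percent contribution of mutation, 100·(1−slope) as selection.

* **ENc–GC3 plot** — each gene's observed ENc against Wright's null
  expectation under pure compositional drift,

      ENc*(s) = 2 + s + 29 / (s² + (1−s)²),   s = GC3 fraction.

  Genes below the curve show selection on codon choice beyond what
  composition explains; genes on it are compatible with composition
  alone; genes above suggest mutational/sampling effects.

* **Parity rule 2 (PR2) plot** — within-strand Chargaff balance at third
  positions, x = A3/(A3+T3) vs y = G3/(G3+C3); (0.5, 0.5) is the
  no-asymmetry point.

Per-nucleotide regressions of overall composition on third-position
composition complete the mutational-pressure picture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .composition import CompositionProfile

__all__ = [
    "expected_enc",
    "NeutralityFit",
    "NeutralityRegression",
    "neutrality_fit",
    "ParityPoint",
    "parity_point",
    "parity_summary",
    "EncGc3Assessment",
    "enc_gc3_assessment",
    "third_position_regressions",
]


def expected_enc(gc3_fraction: float) -> float:
    """Wright's null ENc at synonymous third-position G+C fraction s.

    Symmetric about s = 0.5 where it peaks at 60.5; equals 31 at the
    boundaries s = 0 and s = 1.
    """
    s = float(gc3_fraction)
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3 fraction outside [0, 1]: {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))


# ---------------------------------------------------------------------------
# Neutrality plot


@dataclass(frozen=True)
class NeutralityFit:
    slope: float
    intercept: float
    r_squared: float
    pct_mutation: float
    pct_selection: float
    n_genes: int


class NeutralityRegression(RegressorMixin, BaseEstimator):
    """OLS of GC12 (percent) on GC3 (percent) across a gene panel.

    Follows the scikit-learn estimator contract: ``fit(X, y)`` with X the
    GC3 values (1d or a single column) and y the GC12 values, both in
    percent. Fitted attributes: ``slope_``, ``intercept_``,
    ``r_squared_``, ``pct_mutation_`` (= 100·slope) and
    ``pct_selection_`` (= 100·(1−slope)).
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("GC3 and GC12 must have the same length")
        keep = ~(np.isnan(x) | np.isnan(y))
        x, y = x[keep], y[keep]
        if x.size < 3:
            raise ValueError("need at least 3 genes for the neutrality fit")
        if np.ptp(x) == 0.0:
            raise ValueError("GC3 has zero variance; slope undefined")
        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue) ** 2
        self.pct_mutation_ = 100.0 * self.slope_
        self.pct_selection_ = 100.0 * (1.0 - self.slope_)
        self.n_genes_ = int(x.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * x

    def result_(self) -> NeutralityFit:
        check_is_fitted(self, "slope_")
        return NeutralityFit(
            self.slope_,
            self.intercept_,
            self.r_squared_,
            self.pct_mutation_,
            self.pct_selection_,
            self.n_genes_,
        )


def neutrality_fit(profiles: Sequence[CompositionProfile]) -> NeutralityFit:
    """Convenience wrapper: neutrality regression from composition profiles."""
    gc3 = [p.GC3 for p in profiles]
    gc12 = [p.GC12 for p in profiles]
    return NeutralityRegression().fit(gc3, gc12).result_()


# ---------------------------------------------------------------------------
# Parity rule 2


@dataclass(frozen=True)
class ParityPoint:
    x: float  # A3 / (A3 + T3)
    y: float  # G3 / (G3 + C3)


def parity_point(profile: CompositionProfile) -> ParityPoint:
    """PR2 coordinates of one gene; NaN coordinates on a zero denominator."""
    at = profile.pA3 + profile.pT3
    gc = profile.pG3 + profile.pC3
    x = profile.pA3 / at if at > 0 else float("nan")
    y = profile.pG3 / gc if gc > 0 else float("nan")
    return ParityPoint(x, y)


def parity_summary(
    profiles: Iterable[CompositionProfile],
) -> dict[str, float]:
    """Panel mean ± SD per PR2 axis (genes with undefined axes dropped)."""
    pts = [parity_point(p) for p in profiles]
    xs = np.array([p.x for p in pts])
    ys = np.array([p.y for p in pts])
    xs, ys = xs[~np.isnan(xs)], ys[~np.isnan(ys)]
    return {
        "x_mean": float(np.mean(xs)),
        "x_sd": float(np.std(xs, ddof=1)) if xs.size > 1 else 0.0,
        "y_mean": float(np.mean(ys)),
        "y_sd": float(np.std(ys, ddof=1)) if ys.size > 1 else 0.0,
        "n_genes": int(min(xs.size, ys.size)),
    }


# ---------------------------------------------------------------------------
# ENc vs GC3 curve

BELOW = "BELOW"
ABOVE = "ABOVE"
ON = "ON"


@dataclass(frozen=True)
class EncGc3Assessment:
    """Per-gene placement relative to the drift-null ENc curve."""

    table: pd.DataFrame  # gene_id, gc3, enc, expected_enc, residual, verdict
    tolerance: float
    gc3_policy: str


def enc_gc3_assessment(
    gene_ids: Sequence[str],
    gc3_fraction: Sequence[float],
    enc_values: Sequence[float | None],
    tolerance: float = 0.5,
    gc3_policy: str = "all",
) -> EncGc3Assessment:
    """Compare observed ENc with the drift expectation at each gene's GC3.

    ``tolerance`` is the half-width (ENc units) of the band treated as
    "ON" the curve, since exact equality never occurs with floats.
    ``gc3_policy`` records which GC3 convention produced the x values
    ("all" or "synonymous") and is carried into output metadata only.
    """
    rows = []
    for g, s, e in zip(gene_ids, gc3_fraction, enc_values, strict=True):
        if e is None or (isinstance(e, float) and math.isnan(e)) or math.isnan(s):
            rows.append((g, s, np.nan, np.nan, np.nan, MISSING_VERDICT))
            continue
        exp = expected_enc(s)
        resid = e - exp
        verdict = ON if abs(resid) <= tolerance else BELOW if resid < 0 else ABOVE
        rows.append((g, s, e, exp, resid, verdict))
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "gc3", "enc", "expected_enc", "residual", "verdict"],
    ).set_index("gene_id")
    return EncGc3Assessment(table, tolerance, gc3_policy)


MISSING_VERDICT = "MISSING"


# ---------------------------------------------------------------------------
# Per-nucleotide third-position regressions


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    r_squared: float
    r: float
    p_value: float


def third_position_regressions(
    profiles: Sequence[CompositionProfile],
) -> Mapping[str, RegressionResult]:
    """OLS of overall %N on %N3 for each nucleotide N across the panel.

    R² × 100 is conventionally read as the percent of the nucleotide's
    overall composition explained by third-position (mutational) drift.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 genes")
    out: dict[str, RegressionResult] = {}
    for nuc in "ACGT":
        x = np.array([getattr(p, f"p{nuc}3") for p in profiles])
        y = np.array([getattr(p, f"p{nuc}") for p in profiles])
        if np.ptp(x) == 0.0:
            raise ValueError(f"%{nuc}3 has zero variance; slope undefined")
        res = stats.linregress(x, y)
        out[nuc] = RegressionResult(
            float(res.slope),
            float(res.rvalue) ** 2,
            float(res.rvalue),
            float(res.pvalue),
        )
    return out
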