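"""Dose-response competition fits and exact IC50 -> Ki conversion.

A pre-assembled labeled complex is titrated with an unlabeled
competitor; the signal y vs log10 competitor concentration is fit to a
unit-Hill-slope dose-response model

    y = Ymin + (Ymax - Ymin) / (1 + 10^(x - log10 IC50)),    x = log10[I] (nM),

then normalized to the fraction of complex remaining and (optionally)
refit with the amplitude fixed at 1.0. The inhibition constant is
recovered from the fitted IC50 with the exact Munson-Rodbard
correction, which — unlike the Cheng-Prusoff formula — accounts for
depletion of the competitor's target ligand:

    Ki = IC50 / [1 + L_T (y0 + 2) / (2 K_D (y0 + 1)) + y0] - K_D y0/(y0 + 2)

where L_T is the total concentration of the species the competitor
binds, K_D is the dissociation constant of the pre-assembled labeled
complex, and y0 is that species' bound/free ratio before competitor is
added (obtained from the two-species depletion quadratic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model as LmModel

from .equilibria import TwoSpeciesSystem, bound_complex

__all__ = [
    "CompetitionCurve",
    "DoseResponseFit",
    "KiContext",
    "KiResult",
    "fit_dose_response_raw",
    "normalize_dose_response",
    "initial_bound_free_ratio",
    "ki_exact",
    "DoseResponseModel",
    "DoseResponseResults",
    "OrientationError",
    "KiDomainError",
]

from .binding import FitDegenerateError, _check_not_flat


class OrientationError(ValueError):
    """Signal increases with competitor — not an inhibition curve."""


class KiDomainError(ValueError):
    """The Ki correction produced a non-positive inhibition constant."""


@dataclass
class CompetitionCurve:
    """Competitor titration of a pre-assembled complex.

    ``competitor_total`` may include a zero point; it anchors the upper
    plateau but is excluded from the log-axis regression.
    """

    competitor_total: np.ndarray
    signal: np.ndarray
    replicate_sd: np.ndarray | None = None

    def __post_init__(self):
        self.competitor_total = np.asarray(self.competitor_total, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.replicate_sd is not None:
            self.replicate_sd = np.asarray(self.replicate_sd, dtype=float)
        if self.competitor_total.shape != self.signal.shape:
            raise ValueError("competitor_total and signal must match in length")
        if np.any(self.competitor_total < 0):
            raise ValueError("competitor_total must be non-negative")
        if self.competitor_total.size < 6:
            raise ValueError("need at least 6 competition points")
        pos = self.competitor_total[self.competitor_total > 0]
        if pos.size and pos.max() / pos.min() < 100.0:
            raise ValueError(
                "competitor concentrations must span at least 2 decades"
            )
        order = np.argsort(self.competitor_total, kind="stable")
        self.competitor_total = self.competitor_total[order]
        self.signal = self.signal[order]
        if self.replicate_sd is not None:
            self.replicate_sd = self.replicate_sd[order]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CompetitionCurve":
        cols = set(df.columns)
        if {"competitor_total_nM", "signal", "replicate"} <= cols:
            g = df.groupby("competitor_total_nM")["signal"]
            return cls(g.mean().index.to_numpy(), g.mean().to_numpy(),
                       g.std(ddof=1).fillna(0.0).to_numpy())
        if {"competitor_total_nM", "signal"} <= cols:
            return cls(df["competitor_total_nM"].to_numpy(),
                       df["signal"].to_numpy())
        raise ValueError(
            "competition table needs columns "
            f"'competitor_total_nM, signal[, replicate]'; got {sorted(cols)}"
        )


@dataclass
class DoseResponseFit:
    """Fitted dose-response inhibition parameters."""

    ymin: float
    ymax: float
    log_ic50: float
    standard_errors: dict = field(default_factory=dict)
    ymax_fixed: bool = False

    @property
    def ic50(self) -> float:
        return 10.0 ** self.log_ic50

    @property
    def ic50_stderr(self) -> float | None:
        se = self.standard_errors.get("log_ic50")
        if se is None or not np.isfinite(se):
            return None
        # delta method through 10^x
        return float(self.ic50 * math.log(10.0) * se)


def _dose_response(x, ymin, ymax, log_ic50):
    return ymin + (ymax - ymin) / (1.0 + 10.0 ** (x - log_ic50))


def fit_dose_response_raw(curve: CompetitionCurve,
                          anchor_ymax: bool = True) -> DoseResponseFit:
    """Fit the unit-Hill-slope dose-response model by least squares.

    Zero-competitor points cannot sit on the log axis; when present and
    ``anchor_ymax`` is true they fix Ymax at their mean signal and only
    the positive-concentration points enter the regression.
    """
    mask = curve.competitor_total > 0
    zero_signal = curve.signal[~mask]
    x = np.log10(curve.competitor_total[mask])
    y = curve.signal[mask]
    if x.size < 4:
        raise ValueError("need at least 4 positive-competitor points to fit")
    _check_not_flat(curve.signal)
    slope = np.polyfit(x, y, 1)[0]
    span = float(np.ptp(curve.signal))
    if slope * (x.max() - x.min()) > 0.25 * span:
        raise OrientationError(
            "signal increases with competitor; expected an inhibition "
            "(decreasing) curve"
        )

    fix_ymax = anchor_ymax and zero_signal.size > 0
    ymax0 = float(zero_signal.mean()) if fix_ymax else float(np.max(y))
    ymin0 = float(np.min(y))
    half = ymin0 + 0.5 * (ymax0 - ymin0)
    lic0 = float(x[np.argmin(np.abs(y - half))])

    model = LmModel(_dose_response)
    params = model.make_params(ymin=ymin0, ymax=ymax0, log_ic50=lic0)
    if fix_ymax:
        params["ymax"].set(vary=False)
    out = model.fit(y, params, x=x)
    if not out.success:
        raise FitDegenerateError(f"dose-response fit failed: {out.message}")
    ymin = float(out.params["ymin"].value)
    ymax = float(out.params["ymax"].value)
    if not ymax > ymin or abs(ymax - ymin) <= 1e-10 * max(1.0, abs(ymax)):
        raise FitDegenerateError("fitted dynamic range is degenerate")
    errs = {
        "ymin": out.params["ymin"].stderr,
        "ymax": out.params["ymax"].stderr,
        "log_ic50": out.params["log_ic50"].stderr,
    }
    return DoseResponseFit(ymin, ymax, float(out.params["log_ic50"].value),
                           errs, ymax_fixed=fix_ymax)


def normalize_dose_response(curve: CompetitionCurve,
                            fit: DoseResponseFit) -> CompetitionCurve:
    """Rescale the signal to the fraction of complex remaining.

    F = (y - Ymin)/(Ymax - Ymin); refitting the normalized curve with
    the amplitude fixed at 1.0 leaves the IC50 unchanged on noiseless
    data (the transform is affine).
    """
    span = fit.ymax - fit.ymin
    if span <= 0:
        raise FitDegenerateError("cannot normalize a degenerate fit")
    frac = (curve.signal - fit.ymin) / span
    sd = None if curve.replicate_sd is None else curve.replicate_sd / span
    return CompetitionCurve(curve.competitor_total.copy(), frac, sd)


def initial_bound_free_ratio(lt: float, partner_total: float,
                             kd_complex: float) -> float:
    """Bound/free ratio y0 of the competitor's target before competition.

    The target species (total ``lt``) is pre-equilibrated with its
    labeled partner; y0 = C / (lt - C) with C from the two-species
    depletion quadratic.
    """
    if partner_total == 0:
        return 0.0
    c = bound_complex(TwoSpeciesSystem(lt, partner_total, kd_complex))
    free = lt - c
    if free <= 0:
        raise KiDomainError(
            "target ligand is completely sequestered (bound == total); "
            "y0 is undefined"
        )
    return c / free


@dataclass(frozen=True)
class KiContext:
    """Concentrations needed for the exact IC50 -> Ki correction.

    ``lt`` is the total concentration of the species the competitor
    binds; ``partner_total`` its pre-assembled labeled partner;
    ``kd_complex`` the K_D of that labeled complex. ``y0`` is computed
    from the depletion quadratic unless given explicitly.
    """

    lt: float
    partner_total: float
    kd_complex: float
    y0: float | None = None

    @classmethod
    def from_labeled_ligand(cls, labeled_total: float, binder_total: float,
                            kd_complex: float) -> "KiContext":
        """Exact-inversion assignment: L_T is the labeled tracer.

        With L_T = total labeled ligand and y0 = the tracer's initial
        bound/free ratio, the Munson-Rodbard formula inverts the
        three-species competitive equilibrium exactly (to machine
        precision). ``binder_total`` is the shared species both the
        tracer and the competitor bind.

        Published worked examples in this assay family instead set L_T
        to the species the competitor binds (and take y0 as that
        species' bound/free ratio); use the plain constructor with that
        assignment to reproduce such values.
        """
        return cls(lt=labeled_total, partner_total=binder_total,
                   kd_complex=kd_complex)

    def __post_init__(self):
        if min(self.lt, self.partner_total) < 0 or self.kd_complex <= 0:
            raise ValueError("concentrations must be >= 0 and kd_complex > 0")
        if self.y0 is None:
            object.__setattr__(
                self, "y0",
                initial_bound_free_ratio(self.lt, self.partner_total,
                                         self.kd_complex),
            )
        elif self.y0 < 0:
            raise ValueError("y0 must be >= 0")


@dataclass
class KiResult:
    """Inhibition constant with its provenance."""

    ki: float
    ic50_used: float
    context: KiContext
    ki_stderr: float | None = None


def ki_exact(ic50: float, context: KiContext,
             ic50_stderr: float | None = None) -> KiResult:
    """Exact (Munson-Rodbard) conversion of a fitted IC50 to Ki.

    Ki = IC50 / [1 + L_T(y0+2) / (2 K_D (y0+1)) + y0] - K_D y0/(y0+2).
    A non-positive result means the supplied context is inconsistent
    with the IC50 and raises :class:`KiDomainError`.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    y0 = context.y0
    kd = context.kd_complex
    denom = 1.0 + context.lt * (y0 + 2.0) / (2.0 * kd * (y0 + 1.0)) + y0
    ki = ic50 / denom - kd * y0 / (y0 + 2.0)
    if ki <= 0:
        raise KiDomainError(
            f"Ki = {ki:.4g} nM <= 0: IC50 ({ic50} nM) is inconsistent with "
            f"the supplied context (L_T={context.lt}, K_D={kd}, y0={y0:.4g})"
        )
    se = None if ic50_stderr is None else ic50_stderr / denom
    return KiResult(ki=ki, ic50_used=ic50, context=context, ki_stderr=se)


class DoseResponseModel:
    """Dose-response inhibition model (unit Hill slope).

    ``fit()`` returns a :class:`DoseResponseResults` carrying
    Ymin/Ymax/IC50 with standard errors; ``results.ki(context)`` applies
    the exact Munson-Rodbard correction.
    """

    def __init__(self, curve: CompetitionCurve, anchor_ymax: bool = True):
        self.curve = curve
        self.anchor_ymax = anchor_ymax

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "DoseResponseModel":
        return cls(CompetitionCurve.from_dataframe(df), **kw)

    def fit(self) -> "DoseResponseResults":
        raw = fit_dose_response_raw(self.curve, anchor_ymax=self.anchor_ymax)
        normalized = normalize_dose_response(self.curve, raw)
        return DoseResponseResults(self, raw, normalized)


class DoseResponseResults:
    """Results of :meth:`DoseResponseModel.fit`."""

    def __init__(self, model, raw_fit: DoseResponseFit,
                 normalized: CompetitionCurve):
        self.model = model
        self.raw_fit = raw_fit
        self.normalized = normalized

    @property
    def ic50(self) -> float:
        return self.raw_fit.ic50

    @property
    def ic50_stderr(self) -> float | None:
        return self.raw_fit.ic50_stderr

    @property
    def ymin(self) -> float:
        return self.raw_fit.ymin

    @property
    def ymax(self) -> float:
        return self.raw_fit.ymax

    def ki(self, context: KiContext) -> KiResult:
        """Exact Ki from the fitted IC50 and the assay context."""
        return ki_exact(self.ic50, context, self.ic50_stderr)

    def predict(self, competitor_total: np.ndarray) -> np.ndarray:
        c = np.asarray(competitor_total, dtype=float)
        out = np.full(c.shape, self.ymax, dtype=float)
        pos = c > 0
        out[pos] = _dose_response(np.log10(c[pos]), self.ymin, self.ymax,
                                  self.raw_fit.log_ic50)
        return out

    def summary(self) -> str:
        se = self.ic50_stderr
        se_txt = f"{se:.4g}" if se is not None else "n/a"
        return "\n".join([
            "Dose-response inhibition fit (Hill slope = 1)",
            "=" * 45,
            f"points:   {self.model.curve.signal.size} "
            f"({int(np.sum(self.model.curve.competitor_total == 0))} at zero competitor)",
            f"Ymin:     {self.ymin:.4g} a.u.",
            f"Ymax:     {self.ymax:.4g} a.u."
            + ("  (anchored to zero-competitor signal)" if self.raw_fit.ymax_fixed else ""),
            f"IC50:     {self.ic50:.4g} +/- {se_txt} nM",
        ])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve.competitor_total
        pos = c > 0
        ax.semilogx(c[pos], self.model.curve.signal[pos], "o", label="data")
        grid = np.logspace(np.log10(c[pos].min()), np.log10(c[pos].max()), 200)
        ax.semilogx(grid, self.predict(grid), "-",
                    label=f"fit, IC$_{{50}}$ = {self.ic50:.3g} nM")
        ax.set_xlabel("competitor (nM)")
        ax.set_ylabel("signal (a.u.)")
        ax.legend()
        return ax
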