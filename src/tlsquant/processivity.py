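"""Single-nucleotide-resolution processivity analysis.

Quantified single-turnover primer-extension ladders (product
concentration per insertion position per time point, from gel
densitometry) are reduced to:

* per-step insertion probabilities P_i — the probability that a
  polymerase that has completed insertion i-1 inserts nucleotide i
  rather than dissociating, computed as the termination-probability
  ratio P_i = sum_{j>=i} B_j / sum_{j>=i-1} B_j over extended products
  (j >= 1); P_2 is the abundance of the TLS complex, the population
  that replicates both bases of the di-pyrimidine before dissociating;
* the TLS-complex survival curve y(i) = P_3 * ... * P_i with y(2) = 1;
* processivity extrapolation n = ln(threshold)/ln(P) from a plateau P
  (e.g. P = 0.999 gives ~4600 insertions before 99% of holoenzymes
  have dissociated);
* single-turnover amplitudes (flat-line fit of the total extended
  fraction after a cutoff time) and fold stimulation between
  conditions;
* the surviving-holoenzyme fraction (full-length product over all
  extension products), the readout for polymerase-exchange titrations;
* the kinetic partition P_i = k_pol / (k_pol + k_off).

Pre-incubation misinsertion backgrounds (confined to the first one or
two positions) are subtracted band-wise, clamping at zero.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BandLadder",
    "InsertionProfile",
    "SurvivalCurve",
    "KineticPartition",
    "ProcessivityLength",
    "Amplitude",
    "subtract_preincubation",
    "insertion_probabilities",
    "tls_complex_survival",
    "processivity_length",
    "amplitude_from_timecourse",
    "fold_stimulation",
    "holoenzyme_fraction_remaining",
    "partition_rates",
    "ProcessivityModel",
    "ProcessivityResults",
    "LadderError",
]

logger = logging.getLogger(__name__)


class LadderError(ValueError):
    """Malformed or degenerate band ladder."""


@dataclass
class BandLadder:
    """A quantified primer-extension product ladder.

    ``data`` is a long-form table with columns ``time_s``, ``position``
    (insertion count j; 0 = unextended primer), ``concentration_nM``.
    ``background`` (optional) has the same schema and holds the
    pre-incubation product concentrations; a single-time background is
    broadcast across all time points on subtraction.
    ``full_length_position`` marks the run-off product (e.g. the 62-mer).
    """

    data: pd.DataFrame
    full_length_position: int | None = None
    background: pd.DataFrame | None = None

    def __post_init__(self):
        self.data = self._validate(self.data, "ladder")
        if self.background is not None:
            self.background = self._validate(self.background, "background")

    @staticmethod
    def _validate(df: pd.DataFrame, what: str) -> pd.DataFrame:
        required = {"time_s", "position", "concentration_nM"}
        missing = required - set(df.columns)
        if missing:
            raise LadderError(f"{what} table missing column(s) {sorted(missing)}")
        df = df.copy()
        df["position"] = df["position"].astype(int)
        if (df["concentration_nM"] < 0).any():
            raise LadderError(f"{what} concentrations must be >= 0")
        for t, grp in df.groupby("time_s"):
            pos = np.sort(grp["position"].to_numpy())
            if pos.size != np.unique(pos).size:
                raise LadderError(f"{what}: duplicate positions at t={t}")
            if pos[0] != 0 or not np.array_equal(pos, np.arange(pos.size)):
                raise LadderError(
                    f"{what}: positions at t={t} must be contiguous from 0"
                )
        return df.sort_values(["time_s", "position"]).reset_index(drop=True)

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.data["time_s"].to_numpy())

    def bands(self, time_point: float) -> pd.Series:
        """Concentration per position at one time point."""
        sel = self.data[self.data["time_s"] == time_point]
        if sel.empty:
            raise LadderError(f"no bands at t={time_point}; have t={list(self.times)}")
        return sel.set_index("position")["concentration_nM"]

    @classmethod
    def from_arrays(cls, time_s, position, concentration_nM, **kw) -> "BandLadder":
        return cls(pd.DataFrame({
            "time_s": time_s, "position": position,
            "concentration_nM": concentration_nM}), **kw)


@dataclass
class InsertionProfile:
    """Per-step insertion probabilities; the i = 2 entry is the
    abundance of the TLS complex."""

    step: np.ndarray  # i >= 2, contiguous
    p_i: np.ndarray

    def __post_init__(self):
        self.step = np.asarray(self.step, dtype=int)
        self.p_i = np.asarray(self.p_i, dtype=float)
        if self.step.size != self.p_i.size:
            raise ValueError("step and p_i must have equal length")
        if self.step.size and not np.array_equal(
                self.step, np.arange(self.step[0], self.step[0] + self.step.size)):
            raise ValueError("steps must be contiguous")
        if np.any((self.p_i < 0) | (self.p_i > 1)):
            raise ValueError("p_i must lie in [0, 1]")

    @property
    def p2(self) -> float:
        """TLS-complex abundance (P at step 2)."""
        idx = np.nonzero(self.step == 2)[0]
        if not idx.size:
            raise ValueError("profile does not contain step 2")
        return float(self.p_i[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"step": self.step, "p_i": self.p_i})


@dataclass
class SurvivalCurve:
    """Fraction of the TLS complex surviving to each insertion step."""

    step: np.ndarray
    fraction_remaining: np.ndarray

    def __post_init__(self):
        self.step = np.asarray(self.step, dtype=int)
        self.fraction_remaining = np.asarray(self.fraction_remaining, dtype=float)
        y = self.fraction_remaining
        if y.size:
            if abs(y[0] - 1.0) > 1e-12:
                raise ValueError("survival must start at 1.0")
            if np.any(np.diff(y) > 1e-12):
                raise ValueError("survival must be non-increasing")


@dataclass(frozen=True)
class KineticPartition:
    """(k_pol, k_off, P) triple linked by P = k_pol/(k_pol + k_off)."""

    k_pol: float
    k_off: float
    p: float

    def __post_init__(self):
        expected = self.k_pol / (self.k_pol + self.k_off)
        if abs(self.p - expected) > 1e-12:
            raise ValueError(
                f"partition identity violated: p={self.p} but "
                f"k_pol/(k_pol+k_off)={expected}"
            )

    @classmethod
    def from_rates(cls, k_pol: float, k_off: float) -> "KineticPartition":
        if k_pol <= 0 or k_off < 0:
            raise ValueError("k_pol must be > 0 and k_off >= 0")
        return cls(k_pol, k_off, k_pol / (k_pol + k_off))


@dataclass(frozen=True)
class ProcessivityLength:
    """Extrapolated number of insertions before survival falls below a
    threshold; ``rounded`` follows the 2-significant-figure reporting
    convention."""

    raw: float
    rounded: float
    plateau_p: float
    threshold: float


@dataclass(frozen=True)
class Amplitude:
    """Flat-line amplitude of a single-turnover time course."""

    value: float
    sd: float
    n_points: int


def subtract_preincubation(ladder: BandLadder) -> BandLadder:
    """Subtract pre-incubation product backgrounds band-wise.

    Only extension products (positions >= 1) are subtracted — the
    unextended-primer band is not a product and is left untouched.
    Negative differences are clamped to zero; the number of clamped
    bands is logged and warned about. Background positions must be a
    subset of the ladder's positions.
    """
    corrected, _ = _subtract_preincubation_counted(ladder)
    return corrected


def _subtract_preincubation_counted(ladder: BandLadder) -> tuple[BandLadder, int]:
    if ladder.background is None:
        raise LadderError("ladder carries no background table")
    bg = ladder.background
    data = ladder.data.copy()

    bg_times = np.unique(bg["time_s"].to_numpy())
    extra_pos = set(bg["position"]) - set(data["position"])
    if extra_pos:
        raise LadderError(
            f"background has positions {sorted(extra_pos)} absent from the ladder"
        )
    if bg_times.size == 1:
        bg_map = bg.set_index("position")["concentration_nM"]
        sub = data["position"].map(bg_map).fillna(0.0).to_numpy()
    else:
        if set(bg_times) != set(ladder.times):
            raise LadderError(
                "background time points do not match the ladder "
                f"({list(bg_times)} vs {list(ladder.times)})"
            )
        bg_map = bg.set_index(["time_s", "position"])["concentration_nM"]
        idx = pd.MultiIndex.from_frame(data[["time_s", "position"]])
        sub = bg_map.reindex(idx).fillna(0.0).to_numpy()

    sub = np.where(data["position"].to_numpy() >= 1, sub, 0.0)
    corrected = data["concentration_nM"].to_numpy() - sub
    n_clamped = int(np.sum(corrected < 0))
    if n_clamped:
        msg = (f"pre-incubation subtraction clamped {n_clamped} negative "
               "band(s) to zero")
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    data["concentration_nM"] = np.clip(corrected, 0.0, None)
    out = BandLadder(data, full_length_position=ladder.full_length_position)
    return out, n_clamped


def insertion_probabilities(ladder: BandLadder, time_point: float,
                            noise_floor_fraction: float = 0.01) -> InsertionProfile:
    """Per-step insertion probabilities from one time point's bands.

    P_i = sum_{j>=i} B_j / sum_{j>=i-1} B_j over extended products
    (j >= 1), for i = 2 up to the largest observed position. Steps
    whose denominator falls below ``noise_floor_fraction`` of the total
    extended product are truncated (not reported).
    """
    bands = ladder.bands(time_point)
    positions = bands.index.to_numpy()
    conc = bands.to_numpy()
    ext = positions >= 1
    total_ext = float(conc[ext].sum())
    if total_ext <= 0:
        raise LadderError(
            f"no extension products at t={time_point}; all product is "
            "unextended primer"
        )
    jmax = int(positions.max())
    steps, probs = [], []
    # P_2 is always reportable once any product is extended, even when
    # nothing ran past position 1
    for i in range(2, max(jmax, 2) + 1):
        den = float(conc[(positions >= i - 1) & ext].sum())
        if den < noise_floor_fraction * total_ext:
            break
        num = float(conc[positions >= i].sum())
        steps.append(i)
        probs.append(num / den)
    return InsertionProfile(np.array(steps, dtype=int), np.array(probs))


def tls_complex_survival(profile: InsertionProfile) -> SurvivalCurve:
    """Fraction of the TLS complex remaining at each step.

    y(2) = 1.0 (P_2 normalized to 1) and y(i) = prod_{k=3..i} P_k.
    """
    if not profile.step.size or profile.step[0] != 2:
        raise ValueError("profile must start at step 2 with no gaps")
    y = np.empty(profile.step.size)
    y[0] = 1.0
    for k in range(1, profile.step.size):
        y[k] = y[k - 1] * profile.p_i[k]
    return SurvivalCurve(profile.step.copy(), y)


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def processivity_length(p_plateau: float,
                        survival_threshold: float = 0.010) -> ProcessivityLength:
    """Insertions before survival drops below a threshold.

    n = ln(threshold)/ln(P); reported raw and rounded to 2 significant
    figures (the field's reporting convention, e.g. P = 0.999 ->
    0.999^4600 = 0.010 -> "4600 dNTPs").
    """
    if not 0.0 < p_plateau < 1.0:
        raise ValueError("p_plateau must lie strictly between 0 and 1")
    if not 0.0 < survival_threshold < 1.0:
        raise ValueError("survival_threshold must lie strictly between 0 and 1")
    n = math.log(survival_threshold) / math.log(p_plateau)
    return ProcessivityLength(raw=n, rounded=_round_sig(n, 2),
                              plateau_p=p_plateau,
                              threshold=survival_threshold)


def amplitude_from_timecourse(time, total_extended_fraction,
                              t_min: float = 10.0) -> Amplitude:
    """Flat-line amplitude of a single-turnover time course.

    Points with t > ``t_min`` are fit to a constant; the zero-slope
    least-squares constant is their mean, reported with the sample SD.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(total_extended_fraction, dtype=float)
    sel = t > t_min
    if np.sum(sel) < 2:
        raise ValueError(
            f"need at least 2 points with t > {t_min} s to fit the plateau "
            f"(have {int(np.sum(sel))})"
        )
    vals = y[sel]
    return Amplitude(value=float(vals.mean()),
                     sd=float(vals.std(ddof=1)),
                     n_points=int(vals.size))


def fold_stimulation(amplitude_with, amplitude_without):
    """Ratio of amplitudes with propagated uncertainty.

    Accepts :class:`Amplitude` objects or plain numbers (SD taken as 0);
    relative SDs combine in quadrature. Returns ``(fold, sd)``.
    """
    def unpack(a):
        if isinstance(a, Amplitude):
            return a.value, a.sd
        return float(a), 0.0

    a, sa = unpack(amplitude_with)
    b, sb = unpack(amplitude_without)
    if b == 0:
        raise ZeroDivisionError("reference amplitude is zero")
    fold = a / b
    rel = math.hypot(sa / a if a else 0.0, sb / b)
    return fold, abs(fold) * rel


def holoenzyme_fraction_remaining(ladder: BandLadder,
                                  time_point: float | None = None) -> float:
    """Full-length product over all extension products.

    The fraction of holoenzymes that survived a competitor challenge
    and synthesized to the end of the template.
    """
    if ladder.full_length_position is None:
        raise LadderError("ladder does not define full_length_position")
    if time_point is None:
        time_point = float(ladder.times[-1])
    bands = ladder.bands(time_point)
    ext = bands[bands.index >= 1]
    total = float(ext.sum())
    if total <= 0:
        raise LadderError(f"no extension products at t={time_point}")
    full = float(bands.get(ladder.full_length_position, 0.0))
    return full / total


def partition_rates(p: float, k_pol: float) -> KineticPartition:
    """Kinetic partition: k_off implied by P = k_pol/(k_pol + k_off)."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    if k_pol <= 0:
        raise ValueError("k_pol must be > 0")
    k_off = k_pol * (1.0 - p) / p
    return KineticPartition(k_pol=k_pol, k_off=k_off, p=p)


class ProcessivityModel:
    """Single-turnover primer-extension analysis.

    Bundles background subtraction, the P_i ladder algebra, the
    survival curve, the amplitude time course and (when the ladder
    defines a run-off position) the surviving-holoenzyme fraction::

        res = ProcessivityModel(ladder).fit()
        res.profile.p2, res.survival, res.amplitude
        print(res.summary())

    Parameters
    ----------
    ladder : BandLadder
        May carry its own background table; alternatively pass
        ``background`` (same schema) explicitly.
    noise_floor_fraction : float
        P_i steps whose denominator falls below this fraction of total
        extended product are truncated (default 1%).
    t_min : float
        Amplitude plateau cutoff in seconds (default 10 s).
    """

    def __init__(self, ladder: BandLadder,
                 background: pd.DataFrame | None = None,
                 noise_floor_fraction: float = 0.01,
                 t_min: float = 10.0):
        if background is not None:
            ladder = BandLadder(ladder.data,
                                full_length_position=ladder.full_length_position,
                                background=background)
        self.ladder = ladder
        self.noise_floor_fraction = noise_floor_fraction
        self.t_min = t_min

    def fit(self, time_point: float | None = None) -> "ProcessivityResults":
        """Analyze the ladder at the designated (default last) time point."""
        if self.ladder.background is not None:
            corrected, n_clamped = _subtract_preincubation_counted(self.ladder)
        else:
            corrected, n_clamped = self.ladder, 0
        if time_point is None:
            time_point = float(corrected.times[-1])
        profile = insertion_probabilities(corrected, time_point,
                                          self.noise_floor_fraction)
        survival = tls_complex_survival(profile)

        times = corrected.times
        frac_ext = []
        for t in times:
            bands = corrected.bands(t)
            total = float(bands.sum())
            frac_ext.append(float(bands[bands.index >= 1].sum()) / total
                            if total > 0 else 0.0)
        frac_ext = np.asarray(frac_ext)
        amplitude = None
        if np.sum(times > self.t_min) >= 2:
            amplitude = amplitude_from_timecourse(times, frac_ext, self.t_min)

        holo = None
        if corrected.full_length_position is not None:
            try:
                holo = holoenzyme_fraction_remaining(corrected, time_point)
            except LadderError:
                holo = None
        return ProcessivityResults(self, corrected, time_point, profile,
                                   survival, amplitude, holo, frac_ext,
                                   times, n_clamped)


class ProcessivityResults:
    """Results of :meth:`ProcessivityModel.fit`."""

    def __init__(self, model, corrected_ladder, time_point, profile,
                 survival, amplitude, holoenzyme_fraction,
                 extended_fraction, times, n_clamped):
        self.model = model
        self.corrected_ladder = corrected_ladder
        self.time_point = time_point
        self.profile: InsertionProfile = profile
        self.survival: SurvivalCurve = survival
        self.amplitude: Amplitude | None = amplitude
        self.holoenzyme_fraction: float | None = holoenzyme_fraction
        self.extended_fraction = extended_fraction
        self.times = times
        self.n_clamped = n_clamped

    @property
    def p2(self) -> float:
        return self.profile.p2

    def processivity(self, plateau_p: float | None = None,
                     survival_threshold: float = 0.010) -> ProcessivityLength:
        """Extrapolated processivity from a plateau P (defaults to the
        last reported P_i)."""
        if plateau_p is None:
            plateau_p = float(self.profile.p_i[-1])
        return processivity_length(plateau_p, survival_threshold)

    def summary(self) -> str:
        lines = [
            "Single-turnover processivity analysis",
            "=" * 40,
            f"time point analyzed:  {self.time_point:g} s",
            f"clamped bands:        {self.n_clamped}",
            f"TLS-complex abundance P_2 = {self.p2:.4g}",
            "  i    P_i     survival",
        ]
        for i, p, y in zip(self.profile.step, self.profile.p_i,
                           self.survival.fraction_remaining):
            lines.append(f"  {i:<4d} {p:<7.4g} {y:.4g}")
        if self.amplitude is not None:
            lines.append(
                f"plateau amplitude:    {self.amplitude.value:.4g} "
                f"+/- {self.amplitude.sd:.4g} "
                f"(n={self.amplitude.n_points}, t > {self.model.t_min:g} s)"
            )
        if self.holoenzyme_fraction is not None:
            lines.append(
                f"holoenzyme fraction:  {self.holoenzyme_fraction:.4g}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot P_i and the survival curve vs insertion step."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.profile.step, self.profile.p_i, "s-", label="$P_i$")
        ax.plot(self.survival.step, self.survival.fraction_remaining,
                "o--", label="TLS-complex survival")
        ax.set_xlabel("insertion step $i$")
        ax.set_ylabel("probability / fraction")
        ax.set_ylim(0, 1.05)
        ax.legend()
        return ax
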