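"""Seeded forward simulators for every input class the pipeline consumes.

Each generator draws from the same physical model the analysis assumes:

* equilibrium titrations — signal = C + R * (bound/substrate) + Gaussian
  noise, with the bound complex from the exact two-species depletion
  quadratic at each added-ligand level;
* competition curves — signal proportional to the labeled-bound
  concentration from the exact three-species competitive equilibrium
  over a log-spaced competitor grid (plus a zero anchor point);
* single-turnover product ladders — each engaged primer runs a
  per-step Bernoulli insertion chain (insert nucleotide i with
  probability P_i, else terminate); band counts are multinomial draws
  of ``n_molecules`` scaled to nM, with an additive pre-incubation
  misinsertion background confined to the first two positions;
* polymerase-exchange series — ladders whose full-length (run-off)
  fraction follows the surviving-holoenzyme fraction implied by the
  ternary equilibrium at each dead-competitor concentration.

Default parameter values mirror the assay conditions the package is
designed around: K_D = 120 nM for the labeled polymerase-clamp pair
(20 nM tracer, 200 nM partner), competitor grids spanning 0-5 uM,
10 nM primer/template at 2% signal noise and three replicates.
Identical ``(seed, config)`` pairs produce identical output.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import TitrationCurve, simulated_signal
from .competition import CompetitionCurve
from .equilibria import ThreeSpeciesSystem, competitive_equilibrium
from .processivity import BandLadder

__all__ = [
    "SimulationConfig",
    "simulate_equilibrium_titration",
    "simulate_competition_curve",
    "simulate_single_turnover_ladder",
    "simulate_exchange_series",
    "resolve_config",
]


@dataclass
class SimulationConfig:
    """Configuration for the synthetic generators.

    ``design`` holds concentration grids / time points, ``truth`` the
    generating parameters; keys omitted fall back to the defaults of
    the requested generator (see :func:`resolve_config`). ``noise``
    selects ``"gaussian"``/``"multinomial"`` (per data kind) or
    ``"none"`` for exact expected values.
    """

    seed: int = 0
    noise_sd: float | None = None  # a.u.; None -> 2% of the signal range
    n_molecules: int = 100_000
    noise: str = "default"
    design: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.noise not in ("default", "none"):
            raise ValueError("noise must be 'default' or 'none'")


_TITRATION_DESIGN = {
    "substrate_total_nM": 20.0,
    "n_points": 12,
    "ligand_span": (0.1, 10.0),  # multiples of true K_D, log-spaced
    "replicates": 3,
}
_TITRATION_TRUTH = {"kd_nM": 120.0, "range_r": 1.0, "constant_c": 0.05}

_COMPETITION_DESIGN = {
    "lt_nM": 200.0,          # the species the competitor binds
    "partner_nM": 20.0,      # its pre-assembled labeled partner
    "competitor_max_nM": 5000.0,
    "competitor_min_nM": 5.0,
    "n_points": 12,
    "include_zero": True,
    "replicates": 3,
}
_COMPETITION_TRUTH = {"kd_nM": 120.0, "ki_nM": 111.0,
                      "range_r": 0.8, "constant_c": 0.2}

_LADDER_DESIGN = {
    "primer_total_nM": 10.0,
    "time_points_s": [2.5, 5.0, 10.0, 15.0, 30.0, 60.0],
    "k_obs_s": 0.6,          # single-turnover approach to the plateau
    "max_position": None,    # defaults to the largest insertion step
}
_LADDER_TRUTH = {
    # per-step insertion probabilities (distributive polymerase alone;
    # P_2 is the TLS-complex abundance)
    "p_i": {2: 0.215, 3: 0.30, 4: 0.45, 5: 0.30, 6: 0.15},
    "amplitude": 0.40,       # fraction of primers extended at the plateau
    # pre-incubation misinsertion fractions (of total primer), i <= 2 only
    "background_fractions": {1: 0.02, 2: 0.005},
}

_EXCHANGE_DESIGN = {
    "lt_nM": 10.0,           # target complex the dead competitor binds
    "partner_nM": 50.0,      # pre-assembled labeled polymerase
    "competitor_max_nM": 5000.0,
    "competitor_min_nM": 5.0,
    "n_points": 10,
    "include_zero": True,
    "primer_total_nM": 10.0,
    "full_length_position": 25,
    "extended_fraction": 0.8,
    "quench_time_s": 30.0,
    "early_weights": [0.5, 0.3, 0.2],  # non-surviving product at pos 1..3
}
_EXCHANGE_TRUTH = {"kd_nM": 7.1, "ki_nM": 31.7}


def _merged(defaults: dict, override: dict) -> dict:
    out = copy.deepcopy(defaults)
    out.update(override)
    return out


def resolve_config(kind: str, config: SimulationConfig) -> dict:
    """Fully resolved design/truth for a generator (for truth sidecars)."""
    table = {
        "titration": (_TITRATION_DESIGN, _TITRATION_TRUTH),
        "competition": (_COMPETITION_DESIGN, _COMPETITION_TRUTH),
        "ladder": (_LADDER_DESIGN, _LADDER_TRUTH),
        "exchange": (_EXCHANGE_DESIGN, _EXCHANGE_TRUTH),
    }
    if kind not in table:
        raise ValueError(f"unknown simulation kind {kind!r}")
    design, truth = table[kind]
    return {
        "kind": kind,
        "seed": config.seed,
        "noise_sd": config.noise_sd,
        "n_molecules": config.n_molecules,
        "noise": config.noise,
        "design": _merged(design, config.design),
        "truth": _merged(truth, config.truth),
    }


def _gaussian_sd(config: SimulationConfig, truth: dict) -> float:
    """Additive noise SD: explicit, or 2% of the signal range."""
    if config.noise == "none":
        return 0.0
    if config.noise_sd is not None:
        return config.noise_sd
    return 0.02 * abs(truth["range_r"])


def _replicate_average(clean: np.ndarray, replicates: int, sd: float,
                       rng: np.random.Generator):
    """Draw replicate curves with additive noise; return mean and SD."""
    if sd > 0:
        draws = clean[None, :] + rng.normal(0.0, sd,
                                            size=(replicates, clean.size))
    else:
        draws = np.tile(clean, (replicates, 1))
    mean = draws.mean(axis=0)
    rep_sd = (draws.std(axis=0, ddof=1) if replicates > 1
              else np.zeros_like(mean))
    return mean, rep_sd


def _competitor_grid(design: dict) -> np.ndarray:
    explicit = design.get("competitor_grid")
    if explicit is not None:
        return np.asarray(explicit, dtype=float)
    grid = np.logspace(np.log10(design["competitor_min_nM"]),
                       np.log10(design["competitor_max_nM"]),
                       design["n_points"])
    if design["include_zero"]:
        grid = np.concatenate([[0.0], grid])
    return grid


def simulate_equilibrium_titration(config: SimulationConfig) -> TitrationCurve:
    """Synthetic depletion-corrected binding titration.

    Replicate signals are drawn with additive Gaussian noise and
    averaged point-wise (carrying the SD), matching how replicate
    experiments are reduced before fitting.
    """
    rc = resolve_config("titration", config)
    design, truth = rc["design"], rc["truth"]
    rng = np.random.default_rng(config.seed)

    kd = truth["kd_nM"]
    lo, hi = design["ligand_span"]
    ligand = np.logspace(np.log10(lo * kd), np.log10(hi * kd),
                         design["n_points"])
    clean = simulated_signal(ligand, design["substrate_total_nM"], kd,
                             truth["range_r"], truth["constant_c"])
    mean, rep_sd = _replicate_average(clean, design["replicates"],
                                      _gaussian_sd(config, truth), rng)
    return TitrationCurve(ligand, mean, design["substrate_total_nM"], rep_sd)


def simulate_competition_curve(config: SimulationConfig) -> CompetitionCurve:
    """Synthetic competitor titration of a pre-assembled labeled complex.

    The clean signal is C + R * bound_labeled/bound_labeled(0) from the
    exact three-species equilibrium, so the upper plateau sits at C + R
    and the lower asymptote at C.
    """
    rc = resolve_config("competition", config)
    design, truth = rc["design"], rc["truth"]
    rng = np.random.default_rng(config.seed)

    grid = _competitor_grid(design)
    bound = np.array([
        competitive_equilibrium(ThreeSpeciesSystem(
            total_receptor=design["lt_nM"],
            total_labeled_ligand=design["partner_nM"],
            total_competitor=c,
            kd_labeled=truth["kd_nM"],
            kd_competitor=truth["ki_nM"],
        ))["bound_labeled"]
        for c in grid
    ])
    b0 = competitive_equilibrium(ThreeSpeciesSystem(
        design["lt_nM"], design["partner_nM"], 0.0,
        truth["kd_nM"], truth["ki_nM"]))["bound_labeled"]
    clean = truth["constant_c"] + truth["range_r"] * bound / b0
    mean, rep_sd = _replicate_average(clean, design["replicates"],
                                      _gaussian_sd(config, truth), rng)
    return CompetitionCurve(grid, mean, rep_sd)


def _termination_distribution(p_i: dict, jmax: int) -> np.ndarray:
    """P(terminate at position j | engaged), j = 1..jmax.

    An engaged molecule has inserted nucleotide 1; it proceeds through
    step i with probability P_i (0 beyond the last specified step).
    """
    probs = np.zeros(jmax + 1)  # index j = 0..jmax; engaged never stays at 0
    surv = 1.0
    for j in range(1, jmax + 1):
        p_next = float(p_i.get(j + 1, 0.0))
        probs[j] = surv * (1.0 - p_next)
        surv *= p_next
    return probs


def simulate_single_turnover_ladder(config: SimulationConfig) -> BandLadder:
    """Synthetic single-turnover primer-extension ladder.

    Engaged-molecule counts are binomial in the time-dependent
    amplitude a(t) = A (1 - exp(-k_obs t)); band counts within the
    engaged population are multinomial in the Bernoulli-chain
    termination distribution. The returned ladder carries its matching
    pre-incubation background table (misinsertion confined to
    positions <= 2).
    """
    rc = resolve_config("ladder", config)
    design, truth = rc["design"], rc["truth"]
    rng = np.random.default_rng(config.seed)

    p_i = {int(k): float(v) for k, v in truth["p_i"].items()}
    jmax = design["max_position"] or max(p_i)
    primer = design["primer_total_nM"]
    n = config.n_molecules
    term = _termination_distribution(p_i, jmax)

    bg_fracs = {int(k): float(v) for k, v in truth["background_fractions"].items()}
    if any(k > 2 for k in bg_fracs):
        raise ValueError("pre-incubation misinsertion is confined to positions <= 2")
    bg_conc = np.zeros(jmax + 1)
    for k, frac in bg_fracs.items():
        bg_conc[k] = frac * primer
    bg_conc[0] = primer - bg_conc[1:].sum()

    rows = []
    for t in design["time_points_s"]:
        a_t = truth["amplitude"] * (1.0 - np.exp(-design["k_obs_s"] * t))
        if config.noise == "none":
            counts = n * a_t * term
            counts[0] = n * (1.0 - a_t)
        else:
            n_eng = rng.binomial(n, a_t)
            counts = np.zeros(jmax + 1)
            if n_eng:
                counts[1:] = rng.multinomial(n_eng, term[1:] / term[1:].sum())
            counts[0] = n - n_eng
        conc = counts / n * primer
        # additive pre-incubation products (positions <= 2); the primer
        # band absorbs the complementary amount
        conc = conc * (1.0 - bg_conc[1:].sum() / primer)
        conc[1:] += bg_conc[1:]
        for j in range(jmax + 1):
            rows.append((t, j, conc[j]))
    data = pd.DataFrame(rows, columns=["time_s", "position", "concentration_nM"])
    background = pd.DataFrame({
        "time_s": 0.0,
        "position": np.arange(jmax + 1),
        "concentration_nM": bg_conc,
    })
    return BandLadder(data, full_length_position=None, background=background)


def simulate_exchange_series(config: SimulationConfig) -> tuple[list[BandLadder], np.ndarray]:
    """Synthetic polymerase-exchange titration.

    At each dead-competitor concentration the fraction of surviving
    holoenzymes (those producing full-length product) follows the
    exact ternary equilibrium; each ladder's run-off band carries that
    fraction of the extended product.

    Returns the list of ladders and the matching competitor grid (nM).
    """
    rc = resolve_config("exchange", config)
    design, truth = rc["design"], rc["truth"]
    rng = np.random.default_rng(config.seed)

    grid = _competitor_grid(design)
    b0 = competitive_equilibrium(ThreeSpeciesSystem(
        design["lt_nM"], design["partner_nM"], 0.0,
        truth["kd_nM"], truth["ki_nM"]))["bound_labeled"]
    jfull = design["full_length_position"]
    weights = np.asarray(design["early_weights"], dtype=float)
    weights = weights / weights.sum()
    primer = design["primer_total_nM"]
    ext_frac = design["extended_fraction"]
    t = design["quench_time_s"]
    n = config.n_molecules

    ladders = []
    for comp in grid:
        b = competitive_equilibrium(ThreeSpeciesSystem(
            design["lt_nM"], design["partner_nM"], comp,
            truth["kd_nM"], truth["ki_nM"]))["bound_labeled"]
        f_surv = b / b0
        frac = np.zeros(jfull + 1)
        frac[0] = 1.0 - ext_frac
        frac[jfull] = ext_frac * f_surv
        frac[1:1 + weights.size] = ext_frac * (1.0 - f_surv) * weights
        if config.noise == "none":
            conc = frac * primer
        else:
            counts = rng.multinomial(n, frac)
            conc = counts / n * primer
        data = pd.DataFrame({
            "time_s": t,
            "position": np.arange(jfull + 1),
            "concentration_nM": conc,
        })
        ladders.append(BandLadder(data, full_length_position=jfull))
    return ladders, grid
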