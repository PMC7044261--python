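"""Two-channel combination models and their mapping to observables.

The gain-control model pools the two ears' modulation-depth signals after
mutual divisive suppression::

    resp = C_L^p / (Z^q + C_L^q + w*C_R^q) + C_R^p / (Z^q + C_R^q + w*C_L^q)

where ``C_L, C_R`` are modulation depths in percent, ``w`` (omega) is the
interaural suppression weight, ``Z`` a saturation constant and ``p > q >= 2``
the transducer exponents.  The linear-summation alternative sums depths
before a single binaural transducer::

    resp = (C_L + C_R)^p / (Z^q + (C_L + C_R)^q)

Two readouts connect the response to data:

* psychophysics -- the increment threshold at a pedestal is the smallest
  target depth whose addition raises the model response by the criterion
  ``sigma40`` (one just-discriminable response step);
* steady-state EEG -- the response at a tag frequency maps to a
  signal-to-noise ratio via ``(resp + sigma)/sigma``, so an absent signal
  sits at the nominal SNR floor of 1.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .params import ModelParams
from .stimuli import (
    F35,
    F40,
    MASKER_DEPTH,
    EarSignal,
    EEGCondition,
    PsychCondition,
    eeg_arrangement,
    psych_increment_spec,
)

__all__ = [
    "gain_control_response",
    "linear_sum_response",
    "interval_response",
    "tagged_response",
    "snr_transform",
    "increment_threshold",
    "increment_thresholds",
    "dipper_curve",
    "eeg_response_curve",
    "to_db",
    "from_db",
    "NonBracketableError",
]

# Bracketing range for the threshold search, percent modulation.
BRACKET_LO = 1e-4
BRACKET_HI = 1e4
# Coarse log-grid density (points per decade) used to localize the first
# crossing before bisection; bisection then reduces the bracket far below
# the 1e-6 relative target.
_GRID_PER_DECADE = 20
_BISECT_ITER = 48


class NonBracketableError(RuntimeError):
    """Raised when no target increment in the search range meets the criterion."""


def to_db(depth_pct):
    """Modulation depth in percent -> dB (20*log10 of the percentage)."""
    return 20.0 * np.log10(depth_pct)


def from_db(level_db):
    """dB -> modulation depth in percent."""
    return 10.0 ** (np.asarray(level_db, dtype=float) / 20.0)


def _check_inputs(*arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ValueError("model inputs must be finite and >= 0")


def gain_control_response(C_L, C_R, params: ModelParams):
    """Gain-control model response; symmetric in its two inputs.

    Accepts scalars or broadcastable arrays of percent modulation depth.
    """
    if params.omega is None:
        raise ValueError("gain-control model requires omega")
    cl = np.asarray(C_L, dtype=float)
    cr = np.asarray(C_R, dtype=float)
    _check_inputs(cl, cr)
    p, q, Z, w = params.p, params.q, params.Z, params.omega
    Zq = Z**q
    clq = cl**q
    crq = cr**q
    out = cl**p / (Zq + clq + w * crq) + cr**p / (Zq + crq + w * clq)
    return out if out.ndim else float(out)


def linear_sum_response(C_L, C_R, params: ModelParams):
    """Linear-summation model response; depends only on C_L + C_R."""
    cl = np.asarray(C_L, dtype=float)
    cr = np.asarray(C_R, dtype=float)
    _check_inputs(cl, cr)
    s = cl + cr
    p, q, Z = params.p, params.q, params.Z
    out = s**p / (Z**q + s**q)
    return out if out.ndim else float(out)


_MODELS = {
    "gain": gain_control_response,
    "linear": linear_sum_response,
}


def interval_response(C_L, C_R, params: ModelParams, model: str = "gain"):
    """Response to a same-frequency binaural stimulus under either model."""
    try:
        fn = _MODELS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}; expected 'gain' or 'linear'")
    return fn(C_L, C_R, params)


def tagged_response(
    left: EarSignal,
    right: EarSignal,
    at: float,
    params: ModelParams,
    model: str = "gain",
):
    """Model response read out at one tag frequency.

    Excitation at frequency ``at`` comes only from ears whose modulation
    carries that tag; divisive suppression from the opposite ear pools its
    modulation depth regardless of tag (suppression is untuned for
    modulation frequency).  When both ears carry the same tag this reduces
    exactly to :func:`gain_control_response`.  Under the linear model the
    tagged depths are summed across ears before the transducer and there
    is no cross-frequency interaction.
    """
    if at not in (F40, F35):
        raise ValueError(f"unknown tag frequency {at!r}")
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}")
    el = left.depth if left.tag == at else 0.0
    er = right.depth if right.tag == at else 0.0
    if model == "linear":
        return linear_sum_response(el, er, params)
    if params.omega is None:
        raise ValueError("gain-control model requires omega")
    p, q, Z, w = params.p, params.q, params.Z, params.omega
    Zq = Z**q
    resp = 0.0
    if el > 0:
        resp += el**p / (Zq + el**q + w * right.depth**q)
    if er > 0:
        resp += er**p / (Zq + er**q + w * left.depth**q)
    return float(resp)


def snr_transform(resp, sigma: float):
    """Map a model response to a steady-state SNR: (resp + sigma)/sigma.

    Affine and strictly increasing in ``resp``; equals 1 at resp = 0,
    matching the nominal noise-floor SNR of 1.
    """
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma!r}")
    resp = np.asarray(resp, dtype=float)
    out = (resp + sigma) / sigma
    return out if out.ndim else float(out)


def _delta_response(T, L0, R0, aL, aR, params: ModelParams, model: str):
    """Signed response change when target increment T is added per the masks.

    ``T`` has shape (..., ) broadcastable against the cell arrays.
    """
    fn = _MODELS[model]
    base = fn(L0, R0, params)
    return fn(L0 + aL * T, R0 + aR * T, params) - base


def increment_thresholds(
    conditions: Sequence[PsychCondition | str],
    pedestals: Sequence[float],
    params: ModelParams,
    model: str = "gain",
    criterion: float | None = None,
) -> np.ndarray:
    """Increment thresholds (percent) for paired condition/pedestal cells.

    ``conditions`` and ``pedestals`` are equal-length sequences defining
    the cells.  For each cell the solver returns the smallest target
    increment T whose *signed* response increase over the standard
    interval equals the criterion (``sigma40`` by default): a coarse
    log-spaced scan of [1e-4, 1e4] percent localizes the first upward
    crossing, then bisection refines it well below 1e-6 relative.
    Raises :class:`NonBracketableError`, naming the offending cells, if a
    cell never reaches the criterion in range (or already exceeds it at
    the lower bracket).
    """
    sigma = params.sigma40 if criterion is None else float(criterion)
    if sigma <= 0:
        raise ValueError("criterion must be positive")
    conditions = list(conditions)
    pedestals = np.asarray(list(pedestals), dtype=float)
    if len(conditions) != pedestals.size:
        raise ValueError("conditions and pedestals must have equal length")
    specs = [psych_increment_spec(c, P) for c, P in zip(conditions, pedestals)]
    L0 = np.array([s[0][0] for s in specs])
    R0 = np.array([s[0][1] for s in specs])
    aL = np.array([s[1][0] for s in specs])
    aR = np.array([s[1][1] for s in specs])

    n_dec = np.log10(BRACKET_HI) - np.log10(BRACKET_LO)
    grid = np.logspace(
        np.log10(BRACKET_LO), np.log10(BRACKET_HI), int(n_dec * _GRID_PER_DECADE) + 1
    )
    f = _delta_response(grid[:, None], L0, R0, aL, aR, params, model) - sigma
    # first grid index where the signed increase reaches the criterion
    reached = f >= 0
    if np.any(reached[0]):
        bad = [
            f"{conditions[i]}@{pedestals[i]:g}" for i in np.flatnonzero(reached[0])
        ]
        raise NonBracketableError(
            f"criterion already met at {BRACKET_LO:g}% for cells: {', '.join(bad)}"
        )
    if not np.all(reached.any(axis=0)):
        bad = [
            f"{conditions[i]}@{pedestals[i]:g}"
            for i in np.flatnonzero(~reached.any(axis=0))
        ]
        raise NonBracketableError(
            f"criterion never reached below {BRACKET_HI:g}% for cells: {', '.join(bad)}"
        )
    hi_idx = reached.argmax(axis=0)
    lo = np.log10(grid[hi_idx - 1])
    hi = np.log10(grid[hi_idx])
    for _ in range(_BISECT_ITER):
        mid = 0.5 * (lo + hi)
        fm = _delta_response(10.0**mid, L0, R0, aL, aR, params, model) - sigma
        below = fm < 0
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 10.0 ** (0.5 * (lo + hi))


def increment_threshold(
    condition: PsychCondition | str,
    pedestal: float,
    params: ModelParams,
    model: str = "gain",
    criterion: float | None = None,
) -> float:
    """Scalar convenience wrapper around :func:`increment_thresholds`."""
    return float(
        increment_thresholds([condition], [pedestal], params, model, criterion)[0]
    )


def dipper_curve(
    condition: PsychCondition | str,
    pedestals: Iterable[float],
    params: ModelParams,
    model: str = "gain",
) -> np.ndarray:
    """Predicted discrimination thresholds in dB across pedestal depths.

    Exposes the dipper shape: facilitation (thresholds fall below the
    detection threshold) at small pedestals, then a rising masking handle.
    """
    pedestals = list(pedestals)
    T = increment_thresholds([condition] * len(pedestals), pedestals, params, model)
    return to_db(T)


def eeg_response_curve(
    condition: EEGCondition | str,
    depths: Iterable[float],
    params: ModelParams,
    model: str = "gain",
    masker: float = MASKER_DEPTH,
    freqs: Sequence[float] = (F40, F35),
) -> Mapping[float, np.ndarray]:
    """Predicted steady-state SNR vs signal depth, per tag frequency.

    Uses ``sigma40`` for the 40 Hz readout and ``sigma35`` for 35 Hz;
    requesting a 35 Hz readout without ``sigma35`` raises ``ValueError``.
    """
    condition = EEGCondition(condition)
    sig = {F40: params.sigma40, F35: params.sigma35}
    out: dict[float, np.ndarray] = {}
    for f in freqs:
        if f not in sig:
            raise ValueError(f"unknown tag frequency {f!r}")
        if sig[f] is None:
            raise ValueError("sigma35 is required for a 35 Hz readout")
        vals = []
        for m in depths:
            left, right = eeg_arrangement(condition, m, masker)
            vals.append(
                snr_transform(tagged_response(left, right, f, params, model), sig[f])
            )
        out[f] = np.asarray(vals)
    return out
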