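"""Model parameter bundles and the published fit configurations.

The two-channel gain-control model and the linear-summation model share a
parameter vocabulary:

``p``
    excitatory exponent (dimensionless), constrained to exceed ``q``.
``q``
    suppressive exponent (dimensionless), constrained to be at least 2 so
    the transducer is accelerating enough to produce a dipper.
``Z``
    saturation constant, in the same units as the inputs (percent
    modulation depth).
``omega``
    weight of divisive suppression between the two channels (ears).
    ``None`` for the linear-summation model, which has no interaural
    suppression.
``sigma40`` / ``sigma35``
    noise/criterion parameters in model-response units.  ``sigma40``
    doubles as the psychophysical response-increment criterion at the
    40 Hz modulation frequency; ``sigma35`` is only needed when reading
    out steady-state responses at the 35 Hz tag.

Published parameter sets are shipped as named fixtures keyed by their
figure-panel labels ("6a" ... "7b").
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional

__all__ = ["ModelParams", "TABLE1", "TABLE1_RMSE", "load_params", "dump_params"]

_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Parameter bundle for the binaural combination models.

    Invariants (enforced on construction): all parameters positive,
    ``q >= 2`` and ``p >= q`` (published values are rounded to two
    decimals, so equality is allowed), ``omega >= 0`` where present.
    """

    p: float
    q: float
    Z: float
    sigma40: float
    sigma35: Optional[float] = None
    omega: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("p", "q", "Z", "sigma40"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v!r}")
        if self.q < 2.0 - _TOL:
            raise ValueError(f"q must be >= 2 (got {self.q})")
        if self.p < self.q - _TOL:
            raise ValueError(f"p must be >= q (got p={self.p}, q={self.q})")
        if self.sigma35 is not None and (
            not math.isfinite(self.sigma35) or self.sigma35 <= 0
        ):
            raise ValueError(f"sigma35 must be positive, got {self.sigma35!r}")
        if self.omega is not None and (
            not math.isfinite(self.omega) or self.omega < 0
        ):
            raise ValueError(f"omega must be >= 0, got {self.omega!r}")

    def replace(self, **kwargs) -> "ModelParams":
        d = asdict(self)
        d.update(kwargs)
        return ModelParams(**d)

    def to_dict(self) -> dict:
        return asdict(self)


# Published fits: gain-control rows (6a-6f) and linear-summation rows
# (7a, 7b).  6a/6b/6c fit the discrimination (dipper) data, 6d/6e/6f the
# steady-state EEG data; 6b and 6e are omega->1 evaluations of the free
# fits, 6c and 6f are refits with omega fixed at 1.
TABLE1: dict[str, ModelParams] = {
    "6a": ModelParams(p=2.86, q=2.47, Z=10.22, sigma40=0.88, omega=0.02),
    "6b": ModelParams(p=2.86, q=2.47, Z=10.22, sigma40=0.88, omega=1.0),
    "6c": ModelParams(p=2.13, q=2.00, Z=25.16, sigma40=0.15, omega=1.0),
    "6d": ModelParams(p=2.41, q=2.00, Z=10.94, sigma40=1.85, sigma35=2.55, omega=0.14),
    "6e": ModelParams(p=2.41, q=2.00, Z=10.94, sigma40=1.85, sigma35=2.55, omega=1.0),
    "6f": ModelParams(p=2.00, q=2.00, Z=47.26, sigma40=0.18, sigma35=0.28, omega=1.0),
    "7a": ModelParams(p=2.61, q=2.21, Z=16.14, sigma40=0.72),
    "7b": ModelParams(p=2.61, q=2.00, Z=12.49, sigma40=4.14, sigma35=6.11),
}

# Reported goodness of fit per row; dB units for the dipper fits
# (6a-6c, 7a), linear SNR units for the EEG fits (6d-6f, 7b).
TABLE1_RMSE: dict[str, float] = {
    "6a": 1.2,
    "6b": 5.5,
    "6c": 4.3,
    "6d": 0.34,
    "6e": 0.96,
    "6f": 0.51,
    "7a": 2.4,
    "7b": 0.48,
}


def dump_params(params: ModelParams, path) -> None:
    """Serialize a parameter bundle to JSON ({p, q, Z, omega, sigma40, sigma35})."""
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2)
        fh.write("\n")


def load_params(source) -> ModelParams:
    """Load a parameter bundle from a fixture name, JSON path, or dict."""
    if isinstance(source, ModelParams):
        return source
    if isinstance(source, dict):
        return ModelParams(**source)
    if isinstance(source, str) and source in TABLE1:
        return TABLE1[source]
    with open(source) as fh:
        return ModelParams(**json.load(fh))
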