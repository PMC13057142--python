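"""Quality-control configuration.

All wavenumber ranges, anchor points and thresholds used by the indicators
live in :class:`QCConfig`, so a single YAML file can re-parameterise the
whole pipeline.  The defaults are the values used for the peatland
mid-infrared database QC:

* total-area range [699, 3999] cm^-1 with the CO2 doublet region
  [2250, 2450] cm^-1 linearly interpolated before baseline correction,
* baseline detector: baseline clipped to [1400, 3400] cm^-1, evaluated at
  1400 cm^-1, threshold t_bc = 9e-5 on the area-normalised baseline,
* water-vapor window [3780, 3920] cm^-1 with diagnostic peak at 3853 cm^-1,
* CO2 window [2250, 2450] cm^-1 with diagnostic peak at 2362 cm^-1,
* noise window [2700, 2750] cm^-1, Savitzky-Golay smoother of window 21
  points and polynomial order 3,
* general preprocessing clip [650, 3990] cm^-1.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

Interval = tuple


@dataclass
class QCConfig:
    area_range: Interval = (699.0, 3999.0)
    co2_interp_range: Interval = (2250.0, 2450.0)
    bc_clip_range: Interval = (1400.0, 3400.0)
    bc_eval: float = 1400.0
    t_bc: float = 9e-5
    wv_range: Interval = (3780.0, 3920.0)
    wv_peak_max: float = 3853.0
    co2_range: Interval = (2250.0, 2450.0)
    co2_peak_max: float = 2362.0
    noise_range: Interval = (2700.0, 2750.0)
    savgol_window: int = 21
    savgol_order: int = 3
    preprocess_clip: Interval = (650.0, 3990.0)

    def __post_init__(self) -> None:
        for name in (
            "area_range",
            "co2_interp_range",
            "bc_clip_range",
            "wv_range",
            "co2_range",
            "noise_range",
            "preprocess_clip",
        ):
            a, b = getattr(self, name)
            if not a < b:
                raise ValueError(f"{name} is not a valid interval: [{a}, {b}]")
            setattr(self, name, (float(a), float(b)))
        if self.t_bc <= 0:
            raise ValueError("t_bc must be > 0")
        for peak, rng in (
            (self.wv_peak_max, self.wv_range),
            (self.co2_peak_max, self.co2_range),
        ):
            if not rng[0] <= peak <= rng[1]:
                raise ValueError(f"peak_max {peak} outside its range {rng}")
        if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_order:
            raise ValueError("savgol_window must be odd and > savgol_order")

    @classmethod
    def from_yaml(cls, path) -> "QCConfig":
        """Load a config from YAML; unspecified fields keep their defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in data.items()})

    def to_yaml(self, path) -> None:
        data = {
            k: list(v) if isinstance(v, tuple) else v for k, v in asdict(self).items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
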