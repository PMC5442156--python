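"""Flat pipeline configuration: every tunable default in one place.

Configs round-trip through a plain ``key = value`` text format; unknown
keys are rejected so typos cannot silently fall back to defaults.
"""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    # library / plates
    n_targets: int = 638
    max_sirnas_per_target: int = 5
    plate_rows: int = 16
    plate_cols: int = 24
    include_mitotic_controls: bool = True
    # well simulation
    n_cells: int = 850
    division_rate: float = 0.03          # events/cell/h (~23 h doubling time)
    interphase_death_rate: float = 0.001  # events/cell/h background death
    rate_cv: float = 0.1                  # lognormal well-to-well log-sd
    positive_effect: float = 0.85         # viability controls: rate multiplier 0.15
    mitotic_ctrl_effect: float = 0.15     # mitotic-defect controls: arrest probability
    delay_h: float = 12.0                 # siRNA penetration delay post-transfection
    hit_fraction: float = 0.08            # fraction of library targets with a true phenotype
    hit_effect_min: float = 0.4
    hit_effect_max: float = 0.9
    sirna_failure_rate: float = 0.3       # chance an individual siRNA fails to knock down
    manual_noise_sd: float = 0.5
    # movie geometry
    t_start: float = 4.0
    t_end: float = 72.0
    interval_h: float = 0.5
    frame_px: int = 256
    pixel_um: float = 1.0
    nucleus_radius_um: float = 8.0
    psf_sigma_px: float = 2.0
    background: float = 100.0
    noise_sd: float = 5.0
    brownian_sd_um: float = 2.0
    # fates
    fate_mitotic_death: float = 0.42
    fate_mitotic_exit: float = 0.28
    fate_cytokinesis_failure: float = 0.05
    fate_direct_apoptosis: float = 0.25
    normal_mitosis_h: float = 1.0
    arrest_h: float = 2.0
    arrest_max_h: float = 10.0
    # scoring thresholds
    z_cut: float = 2.0
    mnc_cut: float = 0.8
    manual_cut: int = 3
    # execution
    fast: bool = True

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    def hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_text(Path(path).read_text())

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"line {lineno}: unknown config key {key!r}")
            ftype = fields[key].type
            if ftype == "bool":
                if value not in ("True", "False", "true", "false"):
                    raise ValueError(f"line {lineno}: {key} must be a boolean")
                kwargs[key] = value in ("True", "true")
            elif ftype == "int":
                kwargs[key] = int(value)
            elif ftype == "float":
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)
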