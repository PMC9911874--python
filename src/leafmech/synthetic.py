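"""Model-faithful synthetic force-displacement datasets.

Emulates the measurement chain of the cyclic stress-relaxation
experiments: a ground-truth parameter set drives the uniaxial
material-point simulation, stresses and strains are inverted back to
forces and displacements at the configured sample geometry, and
multiplicative Gaussian noise plus a small additive force floor
(load-cell resolution) are applied per replicate.  Noise acts on the
force — the measured quantity — so the strain/stress conversion path is
exercised by every downstream test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .constitutive import MaterialParameters
from .integration import IntegratorSettings, StressHistory
from .uniaxial import RAMP_STEPS, HOLD_STEPS, ExperimentRecord, build_protocol, uniaxial_response

__all__ = ["GeneratorConfig", "generate_dataset", "make_standard_protocols", "write_dataset"]

#: the three cyclic strain levels (engineering strain)
STRAIN_LEVELS = (0.005, 0.01, 0.02)
#: the three testing speeds in strain/s (1, 10 and 500 % per minute)
RATES = {"1": 0.01 / 60.0, "10": 0.10 / 60.0, "500": 5.00 / 60.0}
#: default hold duration per cycle (s); the experimental holds are not
#: printed, this is the package default and is always stated with results
DEFAULT_HOLD = 300.0
#: tensile clamping length (mm) and a circular petiole cross-section of
#: 2.5 mm diameter as the default geometry
DEFAULT_L0 = 20.0
DEFAULT_AREA = float(np.pi * 1.25**2)


def make_standard_protocols(hold: float = DEFAULT_HOLD) -> dict:
    """Named three-cycle protocols: tension/compression x three speeds.

    Keys are ``tension_1``, ``tension_10``, ``tension_500``,
    ``compression_1``, ``compression_10``, ``compression_500``; all carry
    the 0.5/1/2 % cycles with load-hold-unload at equal load/unload rate.
    """
    out = {}
    for mode, sign in (("tension", 1), ("compression", -1)):
        for label, rate in RATES.items():
            name = f"{mode}_{label}"
            out[name] = build_protocol(STRAIN_LEVELS, rate, hold=hold, sign=sign, name=name)
    return out


@dataclass
class GeneratorConfig:
    """Ground truth, protocol, geometry and noise model of one dataset."""

    parameters: MaterialParameters
    protocol: object
    l0_mm: float = DEFAULT_L0
    area_mm2: float = DEFAULT_AREA
    noise_sigma: float = 0.01          # multiplicative force noise (std, relative)
    force_floor_N: float = 1e-3        # additive noise std (load-cell resolution)
    replicates: int = 5
    seed: int = 0
    ramp_steps: int = RAMP_STEPS
    hold_steps: int = HOLD_STEPS
    tissue: str = ""
    integrator: IntegratorSettings = field(default_factory=IntegratorSettings)

    def __post_init__(self) -> None:
        if self.noise_sigma < 0.0 or self.force_floor_N < 0.0:
            raise ValueError("noise levels must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.l0_mm <= 0.0 or self.area_mm2 <= 0.0:
            raise ValueError("geometry must be positive")


def generate_dataset(cfg: GeneratorConfig) -> tuple[list[ExperimentRecord], StressHistory]:
    """Simulate, invert to force/displacement, and add replicate noise.

    Returns the per-replicate records and the noise-free simulated
    history (the ground-truth curve, e.g. for recovery tests).  The seed
    fixes the output exactly.
    """
    hist = uniaxial_response(
        cfg.protocol,
        cfg.parameters,
        cfg.integrator,
        ramp_steps=cfg.ramp_steps,
        hold_steps=cfg.hold_steps,
    )
    u_clean = (hist.F11 - 1.0) * cfg.l0_mm
    R_clean = hist.P11 * cfg.area_mm2
    rng = np.random.default_rng(cfg.seed)
    records = []
    rate = getattr(cfg.protocol, "name", "") or ""
    for k in range(cfg.replicates):
        R = R_clean * (1.0 + cfg.noise_sigma * rng.standard_normal(R_clean.size))
        R = R + cfg.force_floor_N * rng.standard_normal(R_clean.size)
        records.append(
            ExperimentRecord(
                time_s=hist.time.copy(),
                displacement_mm=u_clean.copy(),
                force_N=R,
                l0_mm=cfg.l0_mm,
                area_mm2=cfg.area_mm2,
                tissue=cfg.tissue,
                rate_label=rate,
            )
        )
    return records, hist


def write_dataset(cfg: GeneratorConfig, outdir) -> list[Path]:
    """Write per-replicate CSVs plus a ground-truth sidecar YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, _ = generate_dataset(cfg)
    paths = []
    for k, rec in enumerate(records):
        path = outdir / f"replicate_{k:02d}.csv"
        rec.to_csv(path)
        paths.append(path)
    sidecar = {
        "ground_truth": cfg.parameters.to_dict(),
        "l0_mm": cfg.l0_mm,
        "area_mm2": cfg.area_mm2,
        "noise_sigma": cfg.noise_sigma,
        "force_floor_N": cfg.force_floor_N,
        "replicates": cfg.replicates,
        "seed": cfg.seed,
        "protocol": getattr(cfg.protocol, "name", None),
        "tissue": cfg.tissue,
    }
    side = outdir / "ground_truth.yaml"
    side.write_text(yaml.safe_dump(sidecar, sort_keys=False))
    paths.append(side)
    return paths
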