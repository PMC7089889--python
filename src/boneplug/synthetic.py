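"""Virtual experimental data: seeded noisy gauge readings and DIC-like
displacement fields, plus the packaged reference validation dataset.

The generator emulates the in vitro instrumentation: four uniaxial surface
strain gauges with independent Gaussian per-reading noise at the published
per-gauge SDs, and a stereo-DIC displacement field with ~1 micrometre
isotropic uncertainty per measurement point.  All draws are fixed by the
seed so a virtual experiment is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import fe
from .geometry import AssemblyMesh
from .validation import PairedSample

__all__ = [
    "NoiseModel",
    "VirtualExperiment",
    "gen_gauge_readings",
    "gen_dic_field",
    "fixtures_table2",
    "reference_tables",
]

#: default load schedule, BW multiples (loading branch of the stepped
#: protocol from 0.33 to 3.5 BW)
DEFAULT_LOAD_STEPS = (0.33, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5)


def reference_tables() -> dict:
    """The packaged reference validation dataset (force components, gauge
    means/SDs, displacement spans) as a nested dict."""
    with resources.files("boneplug.data").joinpath("reference_tables.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: per-gauge strain SD (microstrain) and isotropic
    DIC displacement SD (m), with the seed that fixes all draws."""

    gauge_sd_ue: tuple[float, ...] = (5.2, 8.5, 2.9, 12.7)
    dic_sd_m: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.gauge_sd_ue) or self.dic_sd_m < 0:
            raise ValueError("noise SDs must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class VirtualExperiment:
    """Seeded virtual measurement campaign: gauge readings per load step
    (microstrain) and, optionally, a noisy DIC displacement sample."""

    readings: pd.DataFrame        # index: BW multiple; columns: gauge labels
    load_steps: tuple[float, ...]
    noise: NoiseModel

    def mean_readings(self) -> pd.Series:
        return self.readings.mean(axis=0)


def gen_gauge_readings(truth_ue: dict[str, float] | pd.Series,
                       noise: NoiseModel,
                       steps: tuple[float, ...] = DEFAULT_LOAD_STEPS,
                       repeats: int = 1) -> VirtualExperiment:
    """Virtual gauge readings: linearly scaled unit-load truth plus Gaussian
    per-reading noise.

    ``truth_ue`` maps gauge label -> microstrain at 1.0 BW (linear
    elasticity scales exactly with load).  ``repeats`` emulates repeated
    load cycles at each step.
    """
    truth = pd.Series(truth_ue, dtype=float)
    if len(truth) != len(noise.gauge_sd_ue):
        raise ValueError("one noise SD per gauge required")
    if any(s <= 0 for s in steps):
        raise ValueError("load steps must be positive BW multiples")
    rng = noise.rng()
    rows = []
    index = []
    for step in steps:
        for _ in range(repeats):
            vals = truth.to_numpy() * step + rng.normal(
                0.0, noise.gauge_sd_ue, size=len(truth))
            rows.append(vals)
            index.append(step)
    readings = pd.DataFrame(rows, columns=truth.index,
                            index=pd.Index(index, name="bw_multiple"))
    return VirtualExperiment(readings=readings, load_steps=tuple(steps), noise=noise)


def gen_dic_field(u: fe.DisplacementField | np.ndarray, region: np.ndarray,
                  noise: NoiseModel) -> np.ndarray:
    """Noisy DIC-like displacement sample: per-node 3-vector truth plus
    isotropic Gaussian uncertainty, over the nodes in ``region``."""
    if isinstance(u, fe.DisplacementField):
        u = u.u
    region = np.asarray(region)
    if region.size == 0:
        raise ValueError("empty DIC region")
    rng = noise.rng()
    truth = np.asarray(u)[region]
    return truth + rng.normal(0.0, noise.dic_sd_m, size=truth.shape)


def fixtures_table2() -> dict[str, PairedSample | pd.DataFrame]:
    """The reference gauge-strain and displacement-span pairs as
    :class:`PairedSample` objects (reference = in vitro, predicted =
    in silico) plus the full gauge table."""
    ref = reference_tables()
    g = ref["gauges"]
    d = ref["displacement_spans"]
    gauge_table = pd.DataFrame({
        "gauge": g["labels"],
        "invitro_ue": g["strain_invitro_ue"],
        "invitro_sd_ue": g["strain_invitro_sd_ue"],
        "insilico_ue": g["strain_insilico_ue"],
        "error_pct": g["error_pct"],
    })
    return {
        "strain": PairedSample(np.array(g["strain_invitro_ue"]),
                               np.array(g["strain_insilico_ue"])),
        "spans": PairedSample(np.array(d["invitro_mm"]),
                              np.array(d["insilico_mm"])),
        "gauge_table": gauge_table,
    }
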