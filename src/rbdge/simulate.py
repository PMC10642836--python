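"""Synthetic nCounter cohort generator with known ground truth.

Emulates a PanCancer-style CodeSet (770 endogenous + 30 housekeeping probes,
positive-control ladder, probe-free negatives) hybridized across two tumor
subtypes (URB-like and DRB-like) plus non-tumor controls.  Endogenous counts
are negative-binomial (gamma-Poisson) around lane-scaled log2 baselines; a
configurable fraction of genes carries a symmetric +/- lfc/2 subtype effect,
and a configurable fraction sits at the negative-control background level so
the noise filter has true positives and negatives to find.  Everything is
driven by one seeded RNG, so a config fully determines the dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .rcc import (
    POSITIVE_LADDER_FM,
    CodeSet,
    CountMatrix,
    LaneRecord,
    Probe,
    SampleAnnotation,
    write_annotations,
    write_rcc,
)


class ConfigurationError(ValueError):
    """Raised for invalid simulation parameters."""


# reference-cohort covariate frequencies per subtype, used to draw illustrative
# clinical annotations (documented as illustrative, not inferential).
_COVARIATE_PROPS = {
    "URB": {"male": 9 / 11, "unilateral": 5 / 11, "rb1": 6 / 11,
            "n_stage": (3 / 11, 6 / 11, 2 / 11), "c_stage": (7 / 11, 2 / 11, 2 / 11),
            "age_log2_median": np.log2(14.0)},
    "DRB": {"male": 4 / 10, "unilateral": 6 / 10, "rb1": 2 / 10,
            "n_stage": (4 / 10, 6 / 10, 0.0), "c_stage": (7 / 10, 2 / 10, 1 / 10),
            "age_log2_median": np.log2(10.5)},
}


@dataclass(frozen=True)
class SimulationConfig:
    n_group_a: int = 11          # URB-like samples
    n_group_b: int = 10          # DRB-like samples
    n_controls: int = 2          # non-tumor tissue lanes
    n_endogenous: int = 770
    n_reference: int = 30
    n_pos_controls: int = 6
    n_neg_controls: int = 8
    de_fraction: float = 0.2
    lfc_magnitude: float = 1.5
    nb_dispersion: float = 0.1
    baseline_log_mean_range: tuple[float, float] = (6.0, 12.0)
    lane_factor_sd: float = 0.2
    background_mean: float = 10.0
    background_fraction: float = 0.06
    pos_control_scale: float = 400.0  # counts per fM (max-sensitivity scan)
    seed: int = 0

    def validate(self) -> None:
        positive = {
            "n_group_a": self.n_group_a, "n_group_b": self.n_group_b,
            "n_endogenous": self.n_endogenous, "n_reference": self.n_reference,
            "n_pos_controls": self.n_pos_controls, "n_neg_controls": self.n_neg_controls,
            "lfc_magnitude": self.lfc_magnitude, "nb_dispersion": self.nb_dispersion,
            "background_mean": self.background_mean,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ConfigurationError(f"{name} must be strictly positive, got {value}")
        if self.n_controls < 0:
            raise ConfigurationError("n_controls must be non-negative")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigurationError("de_fraction must lie in [0, 1]")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ConfigurationError("background_fraction must lie in [0, 1]")
        if self.n_group_a + self.n_group_b < 4:
            raise ConfigurationError("need at least 4 tumor samples in total")
        if self.lane_factor_sd < 0:
            raise ConfigurationError("lane_factor_sd must be non-negative")
        lo, hi = self.baseline_log_mean_range
        if not lo <= hi:
            raise ConfigurationError("baseline_log_mean_range must be ordered")


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    annotations: list[SampleAnnotation]
    truth: pd.DataFrame          # index gene; is_de, true_lfc, is_above_noise
    lane_factors: np.ndarray     # per-sample positive scalar
    config: SimulationConfig = field(repr=False, default=None)


def make_codeset(config: SimulationConfig) -> CodeSet:
    """Build the probe panel: endogenous genes, housekeeping references,
    the 128..0.125 fM positive ladder, and probe-free negatives."""
    config.validate()
    probes: list[Probe] = []
    width = len(str(config.n_endogenous))
    for i in range(config.n_endogenous):
        probes.append(Probe("Endogenous", f"GENE_{i + 1:0{width}d}", f"NM_{i + 1:06d}"))
    for i in range(config.n_reference):
        probes.append(Probe("Housekeeping", f"HK_{i + 1:02d}", f"NR_{i + 1:06d}"))
    for i in range(config.n_pos_controls):
        conc = POSITIVE_LADDER_FM[i % len(POSITIVE_LADDER_FM)]
        letter = chr(ord("A") + i)
        probes.append(Probe("Positive", f"POS_{letter}({conc:g})", "ERCC", conc))
    for i in range(config.n_neg_controls):
        probes.append(Probe("Negative", f"NEG_{chr(ord('A') + i)}", "ERCC"))
    return CodeSet(probes, panel_name="SyntheticPanCancer")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson mixture: Var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    config.validate()
    rng = np.random.default_rng(config.seed)
    codeset = make_codeset(config)

    n_tumor = config.n_group_a + config.n_group_b
    n_total = n_tumor + config.n_controls
    group = np.array(
        ["URB"] * config.n_group_a + ["DRB"] * config.n_group_b
        + ["control"] * config.n_controls
    )
    sample_ids = [f"S{i + 1:02d}" for i in range(n_total)]

    if config.lane_factor_sd == 0:
        lane_factors = np.ones(n_total)
    else:
        lane_factors = np.exp(rng.normal(0.0, config.lane_factor_sd, size=n_total))

    genes = codeset.names_of_class("Endogenous")
    G = len(genes)
    lo, hi = config.baseline_log_mean_range
    baselines = rng.uniform(lo, hi, size=G)

    n_bg = int(round(config.background_fraction * G))
    bg_idx = rng.choice(G, size=n_bg, replace=False)
    is_background = np.zeros(G, dtype=bool)
    is_background[bg_idx] = True

    expressed = np.flatnonzero(~is_background)
    n_de = int(round(config.de_fraction * G))
    n_de = min(n_de, expressed.size)
    de_idx = rng.choice(expressed, size=n_de, replace=False)
    is_de = np.zeros(G, dtype=bool)
    is_de[de_idx] = True
    signs = np.where(rng.random(G) < 0.5, 1.0, -1.0)
    true_lfc = np.where(is_de, signs * config.lfc_magnitude, 0.0)

    # half-effect per group keeps the total library balanced
    effect = np.zeros((G, n_total))
    effect[:, group == "URB"] = (true_lfc / 2.0)[:, None]
    effect[:, group == "DRB"] = (-true_lfc / 2.0)[:, None]

    log_mean = baselines[:, None] + effect
    endo_mean = lane_factors[None, :] * np.exp2(log_mean)
    # background genes behave like the probe-free negatives
    endo_mean[is_background] = config.background_mean * lane_factors[None, :]
    endo_counts = _nb_draw(rng, endo_mean, config.nb_dispersion)

    # housekeeping genes sit in the upper half of the baseline range (stably
    # and well expressed by design of the panel)
    hk_baselines = rng.uniform(lo + 0.5 * (hi - lo), hi, size=config.n_reference)
    hk_mean = lane_factors[None, :] * np.exp2(hk_baselines)[:, None]
    hk_counts = _nb_draw(rng, hk_mean, config.nb_dispersion)

    pos_conc = np.array(
        [p.expected_concentration for p in codeset.probes if p.code_class == "Positive"]
    )
    pos_mean = lane_factors[None, :] * config.pos_control_scale * pos_conc[:, None]
    pos_counts = rng.poisson(pos_mean)

    neg_mean = np.full((config.n_neg_controls, n_total), config.background_mean)
    neg_counts = rng.poisson(neg_mean * lane_factors[None, :])

    values = np.vstack([endo_counts, hk_counts, pos_counts, neg_counts]).astype(float)
    counts = CountMatrix(codeset, sample_ids, values)

    annotations = _draw_annotations(rng, sample_ids, group)

    truth = pd.DataFrame(
        {
            "is_de": is_de,
            "true_lfc": true_lfc,
            "is_above_noise": ~is_background,
        },
        index=pd.Index(genes, name="gene"),
    )
    return SimulatedDataset(counts, annotations, truth, lane_factors, config)


def _draw_annotations(
    rng: np.random.Generator, sample_ids: list[str], group: np.ndarray
) -> list[SampleAnnotation]:
    records = []
    for sid, subtype in zip(sample_ids, group):
        props = _COVARIATE_PROPS["URB" if subtype == "URB" else "DRB"]
        age = float(np.round(np.exp2(rng.normal(props["age_log2_median"], 0.8))))
        age = float(np.clip(age, 2.0, 60.0))
        records.append(
            SampleAnnotation(
                sample_id=sid,
                subtype=subtype,
                sex="male" if rng.random() < props["male"] else "female",
                laterality="unilateral" if rng.random() < props["unilateral"] else "bilateral",
                age_months=age,
                n_stage=f"N{rng.choice(3, p=np.asarray(props['n_stage']) / sum(props['n_stage']))}",
                c_stage=f"C{rng.choice(3, p=np.asarray(props['c_stage']) / sum(props['c_stage']))}",
                rb1_germline=bool(rng.random() < props["rb1"]),
            )
        )
    return records


def write_dataset(dataset: SimulatedDataset, directory: str | Path) -> dict:
    """Write one RCC per sample plus annotations.csv and truth.csv.

    Returns a manifest mapping artifact kinds to file paths; round-trips
    losslessly through :mod:`rbdge.rcc`.
    """
    if not str(directory):
        raise OSError("empty output directory")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    rcc_files = []
    for j, sid in enumerate(dataset.counts.sample_ids):
        lane = LaneRecord(
            sample_id=sid,
            lane_attributes={"ID": str(j + 1), "FovCount": "555", "FovCounted": "555"},
            counts={
                p.name: int(dataset.counts.values[i, j])
                for i, p in enumerate(dataset.counts.codeset.probes)
            },
        )
        path = directory / f"{sid}.RCC"
        write_rcc(lane, dataset.counts.codeset, path)
        rcc_files.append(str(path))

    ann_path = directory / "annotations.csv"
    write_annotations(dataset.annotations, ann_path)
    truth_path = directory / "truth.csv"
    dataset.truth.to_csv(truth_path)

    manifest = {
        "rcc_files": rcc_files,
        "annotations": str(ann_path),
        "truth": str(truth_path),
        "n_samples": len(dataset.counts.sample_ids),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def config_from_dict(payload: dict) -> SimulationConfig:
    known = {f for f in SimulationConfig.__dataclass_fields__}
    unknown = set(payload) - known
    if unknown:
        raise ConfigurationError(f"unknown simulation parameters: {sorted(unknown)}")
    if "baseline_log_mean_range" in payload:
        payload = dict(payload)
        payload["baseline_log_mean_range"] = tuple(payload["baseline_log_mean_range"])
    return SimulationConfig(**payload)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["baseline_log_mean_range"] = list(d["baseline_log_mean_range"])
    return d
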