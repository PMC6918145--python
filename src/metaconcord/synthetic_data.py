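"""Seeded simulator of multi-laboratory two-sample triplicate studies.

The generator emulates the structure of a ring-trial dataset — two cell
extract pools measured in triplicate by several independent analytical
methods with partially overlapping metabolite coverage — together with
ground-truth labels, so that the concordance cascade can be validated
end to end without any external data.

Signal model, per covered metabolite and replicate::

    intensity = response * abundance(sample) * exp(eps),   eps ~ N(0, sigma)

where ``abundance(ASPC1)`` is a log-normal base abundance,
``abundance(HT29) = base * true_ratio``, ``response`` is a method- and
metabolite-specific sensitivity factor (arbitrary units; the cascade is
invariant to it), and ``sigma`` equals the method's replicate coefficient
of variation (first-order log-normal approximation).  Values below the
method's limit of detection are reported missing, so sensitivity
differences surface as dropped methods rather than zeros.

Four fault mechanisms, mirroring failure modes diagnosed in real
inter-laboratory comparisons, can be injected per method:

* **coelution** — the intensities of an isomer group are summed into one
  reported peak, dragging the reported ratio toward the group's
  intensity-weighted mean ratio;
* **isobaric_overlap** — a fraction of a contaminant compound's signal
  leaks into a target's peak (overlapping MRM transitions);
* **misidentification** — the method reports compound X but integrated
  compound Y's peak;
* **derivatization_bias** — sample-dependent multiplicative recovery
  factors (an incomplete derivatization reaction that hits one matrix
  harder than the other), directly biasing the reported ratio.

Faults are applied in the fixed order coelution -> isobaric_overlap ->
misidentification -> derivatization_bias (identification errors before
sample-dependent bias); the order only matters when faults co-occur on one
cell.  All randomness flows through a single seeded generator, so one seed
plus one config yields byte-identical output files.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    SAMPLES,
    CATEGORIES,
    IntegratedDataset,
    MethodInfo,
)
from .nomenclature import CompoundRecord

__all__ = [
    "Fault",
    "MethodModel",
    "TruthProfile",
    "SimulationConfig",
    "SimulatedStudy",
    "generate_truth",
    "simulate_method",
    "simulate_study",
]

FAULT_KINDS = (
    "coelution",
    "isobaric_overlap",
    "misidentification",
    "derivatization_bias",
)


@dataclass
class Fault:
    """One injected error mechanism on one method.

    Parameter use by kind:
      coelution            — ``group`` (member ids; summed), ``reported_id``
                             (the member the merged peak is reported under).
      isobaric_overlap     — ``target_id``, ``contaminant_id``, ``fraction``
                             in [0, 1].
      misidentification    — ``reported_id`` (what the method claims),
                             ``source_id`` (whose peak it integrated).
      derivatization_bias  — ``metabolites`` (empty = all covered),
                             ``f_ht29``/``f_aspc1`` multiplicative factors.
    """

    kind: str
    group: tuple[str, ...] = ()
    reported_id: Optional[str] = None
    source_id: Optional[str] = None
    target_id: Optional[str] = None
    contaminant_id: Optional[str] = None
    fraction: float = 0.0
    metabolites: tuple[str, ...] = ()
    f_ht29: float = 1.0
    f_aspc1: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in FAULT_KINDS:
            raise ValueError(f"unknown fault kind {self.kind!r}")
        if self.kind == "coelution":
            if len(self.group) < 2:
                raise ValueError("coelution needs an isomer group of >= 2 members")
            if self.reported_id is None:
                object.__setattr__(self, "reported_id", self.group[0])
            if self.reported_id not in self.group:
                raise ValueError("coelution reported_id must belong to the group")
        elif self.kind == "isobaric_overlap":
            if not self.target_id or not self.contaminant_id:
                raise ValueError("isobaric_overlap needs target_id and contaminant_id")
            if not (0.0 <= self.fraction <= 1.0):
                raise ValueError("contamination fraction must be in [0, 1]")
        elif self.kind == "misidentification":
            if not self.reported_id or not self.source_id:
                raise ValueError("misidentification needs reported_id and source_id")
        elif self.kind == "derivatization_bias":
            if self.f_ht29 <= 0 or self.f_aspc1 <= 0:
                raise ValueError("derivatization factors must be > 0")

    def affected(self, coverage: Iterable[str]) -> set[str]:
        """The metabolite ids whose reported values this fault perturbs."""
        if self.kind == "coelution":
            return set(self.group)
        if self.kind == "isobaric_overlap":
            return {self.target_id}
        if self.kind == "misidentification":
            return {self.reported_id}
        targets = set(self.metabolites) if self.metabolites else set(coverage)
        return targets


@dataclass
class MethodModel:
    """The simulator's view of one analytical method."""

    method_id: str
    category: str
    coverage: tuple[str, ...]
    response: dict[str, float]
    cv: float
    lod: Optional[float] = None
    faults: tuple[Fault, ...] = ()

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("replicate CV must be >= 0")
        missing = [m for m in self.coverage if m not in self.response]
        if missing:
            raise ValueError(f"no response factor for covered metabolites {missing}")


@dataclass
class TruthProfile:
    """Ground truth: per-metabolite base abundance (AsPc-1 side), true
    HT-29/AsPc-1 ratio (1.0 for nulls) and category."""

    base_abundance: dict[str, float]
    true_ratio: dict[str, float]
    category: dict[str, str]

    @property
    def metabolites(self) -> list[str]:
        return sorted(self.base_abundance)

    def abundance(self, metabolite: str, sample: str) -> float:
        base = self.base_abundance[metabolite]
        if sample == "HT29":
            return base * self.true_ratio[metabolite]
        return base


@dataclass
class SimulationConfig:
    """Study-design knobs for the simulator (serializable as YAML).

    ``mean_methods_per_metabolite`` controls the partial-coverage structure:
    each metabolite is independently included in each method's panel with
    probability mean/n_methods (full coverage when equal)."""

    seed: int
    n_hydrophilic: int = 40
    n_hydrophobic: int = 60
    n_methods_hydrophilic: int = 5
    n_methods_hydrophobic: int = 4
    mean_methods_per_metabolite: float = 3.0
    fraction_nonnull: float = 0.3
    effect_log_sd: float = 0.7
    abundance_log_mean: float = 11.5
    abundance_log_sd: float = 1.0
    response_log_sd: float = 0.5
    cv_range: tuple[float, float] = (0.05, 0.15)
    lod_quantile: float = 0.02
    n_replicates: int = 3
    faults: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("simulation seed is mandatory")
        self.seed = int(self.seed)
        for name in (
            "n_hydrophilic",
            "n_hydrophobic",
            "n_methods_hydrophilic",
            "n_methods_hydrophobic",
            "n_replicates",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.fraction_nonnull <= 1.0):
            raise ValueError("fraction_nonnull must be in [0, 1]")
        lo, hi = self.cv_range
        if lo < 0 or hi < lo:
            raise ValueError("cv_range must satisfy 0 <= lo <= hi")
        if not (0.0 <= self.lod_quantile < 1.0):
            raise ValueError("lod_quantile must be in [0, 1)")
        self.cv_range = (float(lo), float(hi))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        if "seed" not in raw:
            raise ValueError(f"{path}: simulation seed is mandatory")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config field(s) {sorted(unknown)}")
        if "cv_range" in raw:
            raw["cv_range"] = tuple(raw["cv_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        Path(path).write_text(
            yaml.safe_dump(data, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def demo(cls, seed: int = 20180401) -> "SimulationConfig":
        """A small demonstration study: five hydrophilic and four
        hydrophobic methods, one fault of each mechanism."""
        return cls(
            seed=seed,
            n_hydrophilic=40,
            n_hydrophobic=60,
            n_methods_hydrophilic=5,
            n_methods_hydrophobic=4,
            mean_methods_per_metabolite=3.5,
            fraction_nonnull=0.3,
            faults=[
                {
                    "category": "hydrophilic",
                    "method_id": "E",
                    "kind": "derivatization_bias",
                    "metabolites": ["hilic_0003", "hilic_0007"],
                    "f_ht29": 0.4,
                    "f_aspc1": 1.0,
                },
                {
                    "category": "hydrophilic",
                    "method_id": "B",
                    "kind": "isobaric_overlap",
                    "target_id": "hilic_0010",
                    "contaminant_id": "hilic_0011",
                    "fraction": 0.5,
                },
                {
                    "category": "hydrophobic",
                    "method_id": "A",
                    "kind": "coelution",
                    "group": ["lipid_0001", "lipid_0002"],
                    "reported_id": "lipid_0001",
                },
                {
                    "category": "hydrophobic",
                    "method_id": "C",
                    "kind": "misidentification",
                    "reported_id": "lipid_0005",
                    "source_id": "lipid_0006",
                },
            ],
        )


@dataclass
class SimulatedStudy:
    dataset: IntegratedDataset
    labels: pd.DataFrame  # metabolite, category, method_id, fault_kind, true_ratio
    truth: TruthProfile
    models: list[MethodModel]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_truth(
    config: SimulationConfig, rng: np.random.Generator
) -> TruthProfile:
    """Draw per-metabolite base abundances and true HT-29/AsPc-1 ratios.

    Non-null metabolites get a log-normal effect symmetric on the log scale
    (so up- and down-regulation are equally reachable); nulls have ratio
    exactly 1."""
    base: dict[str, float] = {}
    ratio: dict[str, float] = {}
    category: dict[str, str] = {}
    for cat, n, prefix in (
        ("hydrophilic", config.n_hydrophilic, "hilic"),
        ("hydrophobic", config.n_hydrophobic, "lipid"),
    ):
        for i in range(n):
            met = f"{prefix}_{i:04d}"
            base[met] = float(
                np.exp(rng.normal(config.abundance_log_mean, config.abundance_log_sd))
            )
            if rng.random() < config.fraction_nonnull:
                r = float(np.exp(rng.normal(0.0, config.effect_log_sd)))
                ratio[met] = r if r != 1.0 else float(np.exp(config.effect_log_sd))
            else:
                ratio[met] = 1.0
            category[met] = cat
    return TruthProfile(base_abundance=base, true_ratio=ratio, category=category)


def _method_ids(n: int) -> list[str]:
    letters = string.ascii_uppercase
    if n <= len(letters):
        return list(letters[:n])
    return [f"M{i:02d}" for i in range(1, n + 1)]


def simulate_method(
    truth: TruthProfile,
    model: MethodModel,
    rng: np.random.Generator,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulate one method's replicate intensities over its coverage.

    Returns a measurements frame (method_id, category, metabolite, sample,
    replicate, intensity) with NaN for below-LOD values.  Faults are applied
    in the documented order after noise generation, so a coeluting peak sums
    the members' noisy signals as an integrator would.
    """
    # signal ids whose raw intensities we must generate: coverage plus any
    # compound a fault pulls signal from
    needed = set(model.coverage)
    for fault in model.faults:
        if fault.kind == "coelution":
            needed.update(fault.group)
        elif fault.kind == "isobaric_overlap":
            needed.add(fault.contaminant_id)
        elif fault.kind == "misidentification":
            needed.add(fault.source_id)

    raw: dict[str, dict[str, np.ndarray]] = {}
    for met in sorted(needed):
        resp = model.response.get(met, 1.0)
        raw[met] = {}
        for sample in SAMPLES:
            mu = resp * truth.abundance(met, sample)
            noise = (
                rng.normal(0.0, model.cv, size=n_replicates)
                if model.cv > 0
                else np.zeros(n_replicates)
            )
            raw[met][sample] = mu * np.exp(noise)

    reported: dict[str, dict[str, np.ndarray]] = {
        met: {s: raw[met][s].copy() for s in SAMPLES} for met in model.coverage
    }

    for fault in model.faults:
        if fault.kind == "coelution":
            merged = {
                s: sum(raw[m][s] for m in fault.group) for s in SAMPLES
            }
            reported[fault.reported_id] = {s: merged[s].copy() for s in SAMPLES}
            for member in fault.group:
                if member != fault.reported_id:
                    reported.pop(member, None)
    for fault in model.faults:
        if fault.kind == "isobaric_overlap" and fault.target_id in reported:
            for s in SAMPLES:
                reported[fault.target_id][s] = (
                    reported[fault.target_id][s]
                    + fault.fraction * raw[fault.contaminant_id][s]
                )
    for fault in model.faults:
        if fault.kind == "misidentification" and fault.reported_id in reported:
            reported[fault.reported_id] = {
                s: raw[fault.source_id][s].copy() for s in SAMPLES
            }
    for fault in model.faults:
        if fault.kind == "derivatization_bias":
            targets = fault.affected(model.coverage) & set(reported)
            for met in targets:
                reported[met]["HT29"] = reported[met]["HT29"] * fault.f_ht29
                reported[met]["ASPC1"] = reported[met]["ASPC1"] * fault.f_aspc1

    rows = []
    for met in sorted(reported):
        for sample in SAMPLES:
            values = reported[met][sample]
            for rep in range(1, n_replicates + 1):
                v = float(values[rep - 1])
                if model.lod is not None and v < model.lod:
                    v = float("nan")
                rows.append((model.method_id, model.category, met, sample, rep, v))
    return pd.DataFrame(
        rows,
        columns=["method_id", "category", "metabolite", "sample", "replicate", "intensity"],
    )


def _build_models(
    config: SimulationConfig, truth: TruthProfile, rng: np.random.Generator
) -> list[MethodModel]:
    fault_specs: dict[tuple[str, str], list[Fault]] = {}
    for spec in config.faults:
        spec = dict(spec)
        cat = spec.pop("category")
        mid = spec.pop("method_id")
        for key in ("group", "metabolites"):
            if key in spec:
                spec[key] = tuple(spec[key])
        fault_specs.setdefault((cat, mid), []).append(Fault(**spec))

    models: list[MethodModel] = []
    for cat, n_methods in (
        ("hydrophilic", config.n_methods_hydrophilic),
        ("hydrophobic", config.n_methods_hydrophobic),
    ):
        mets = sorted(m for m in truth.metabolites if truth.category[m] == cat)
        p_cover = min(1.0, config.mean_methods_per_metabolite / n_methods)
        for method_id in _method_ids(n_methods):
            covered = [m for m in mets if rng.random() < p_cover]
            faults = tuple(fault_specs.get((cat, method_id), ()))
            # fault-referenced metabolites must be reportable by the method
            must_cover: set[str] = set()
            for fault in faults:
                if fault.kind == "coelution":
                    must_cover.add(fault.reported_id)
                elif fault.kind == "isobaric_overlap":
                    must_cover.add(fault.target_id)
                elif fault.kind == "misidentification":
                    must_cover.add(fault.reported_id)
                else:
                    must_cover.update(fault.metabolites)
            covered = sorted(set(covered) | (must_cover & set(mets)))
            response = {
                m: float(np.exp(rng.normal(0.0, config.response_log_sd)))
                for m in mets
            }
            cv = float(rng.uniform(*config.cv_range))
            lod = None
            if config.lod_quantile > 0 and covered:
                noiseless = np.array(
                    [
                        response[m] * truth.abundance(m, s)
                        for m in covered
                        for s in SAMPLES
                    ]
                )
                lod = float(np.quantile(noiseless, config.lod_quantile))
            models.append(
                MethodModel(
                    method_id=method_id,
                    category=cat,
                    coverage=tuple(covered),
                    response=response,
                    cv=cv,
                    lod=lod,
                    faults=faults,
                )
            )
    return models


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a full study: dataset (validated against the schema) plus a
    ground-truth label table aligned 1:1 with the simulated method x
    metabolite cells."""
    rng = np.random.default_rng(config.seed)
    truth = generate_truth(config, rng)
    models = _build_models(config, truth, rng)

    frames = [
        simulate_method(truth, model, rng, n_replicates=config.n_replicates)
        for model in models
    ]
    measurements = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["method_id", "category", "metabolite", "sample", "replicate", "intensity"]
        )
    )

    methods = [
        MethodInfo(
            method_id=m.method_id,
            lab_id=f"L{i + 1}",
            category=m.category,
            platform="simulated",
            analytical_mode="simulated",
        )
        for i, m in enumerate(models)
    ]
    compounds = [
        CompoundRecord(
            canonical_id=met,
            display_name=met,
            category=truth.category[met],
            synonyms=set(),
        )
        for met in truth.metabolites
    ]

    label_rows = []
    for model in models:
        fault_by_met: dict[str, str] = {}
        for fault in model.faults:
            for met in fault.affected(model.coverage):
                prev = fault_by_met.get(met)
                fault_by_met[met] = f"{prev}+{fault.kind}" if prev else fault.kind
        reported_ids = sorted(
            set(measurements.loc[
                (measurements["category"] == model.category)
                & (measurements["method_id"] == model.method_id),
                "metabolite",
            ])
        )
        for met in reported_ids:
            label_rows.append(
                {
                    "metabolite": met,
                    "category": model.category,
                    "method_id": model.method_id,
                    "fault_kind": fault_by_met.get(met, ""),
                    "true_ratio": truth.true_ratio[met],
                }
            )
        # coelution removes non-reported members from the output; flag them
        # in the labels anyway so the bookkeeping names every affected id
        for met in sorted(set(fault_by_met) - set(reported_ids)):
            label_rows.append(
                {
                    "metabolite": met,
                    "category": model.category,
                    "method_id": model.method_id,
                    "fault_kind": fault_by_met[met],
                    "true_ratio": truth.true_ratio.get(met, float("nan")),
                }
            )
    labels = pd.DataFrame(
        label_rows,
        columns=["metabolite", "category", "method_id", "fault_kind", "true_ratio"],
    )

    dataset = IntegratedDataset(
        methods=methods,
        measurements=measurements,
        compounds=compounds,
        max_replicates=config.n_replicates,
    )
    return SimulatedStudy(dataset=dataset, labels=labels, truth=truth, models=models)


def write_labels(labels: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = labels.copy()
    out["true_ratio"] = out["true_ratio"].map(lambda v: repr(float(v)))
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path
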