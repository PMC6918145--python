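"""Schema, validation and I/O for the integrated multi-method dataset.

The unit of data is one replicate intensity reading: a method (an analytical
pipeline at one laboratory) measured one metabolite in one of two cell-line
extract samples (HT-29 colorectal adenocarcinoma vs AsPc-1 pancreatic
cancer), in one of three replicate runs.  Intensities are arbitrary signal
units that differ wildly between methods; only within-method HT-29/AsPc-1
ratios are comparable, which is what the concordance cascade consumes.

Two bookkeeping conventions matter downstream:

* Missing intensities are empty fields (NaN), not zeros.  A zero is a valid
  sub-detection-limit signal; a missing field means the method did not
  report the compound in that run.  Limit-of-detection differences between
  methods therefore surface as missingness, not as spurious zeros.
* A method "detects" a metabolite in a sample when at least
  ``min_replicates`` (default 2) of its replicate intensities are present —
  tolerant of one failed run, robust to singleton artifacts.  The threshold
  is configurable.

Method identifiers (letters) are reused between the hydrophilic and
hydrophobic panels, so the working key for a method is (category,
method_id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .nomenclature import (
    ClassRegistry,
    CompoundRecord,
    NomenclatureError,
    default_registry,
    harmonize_ids,
    parse_lipid_name,
    read_synonyms_tsv,
)

__all__ = [
    "SAMPLES",
    "CATEGORIES",
    "DatasetError",
    "MethodInfo",
    "IntegratedDataset",
    "CoverageCounts",
    "read_dataset",
    "write_dataset",
    "detected",
    "coverage_counts",
]

logger = logging.getLogger(__name__)

SAMPLES = ("HT29", "ASPC1")
CATEGORIES = ("hydrophilic", "hydrophobic")

MEASUREMENT_COLUMNS = [
    "method_id",
    "category",
    "metabolite",
    "sample",
    "replicate",
    "intensity",
]
METHOD_COLUMNS = ["method_id", "lab_id", "category", "analytical_method", "analytical_mode"]
COMPOUND_COLUMNS = ["canonical_id", "display_name", "category", "synonyms"]


class DatasetError(ValueError):
    """Raised when a dataset file or in-memory dataset violates the schema."""


@dataclass(frozen=True)
class MethodInfo:
    """One analytical method: platform metadata mirroring a ring-trial
    method table (method letter, lab, separation/detection platform, mode)."""

    method_id: str
    lab_id: str
    category: str
    platform: str = ""
    analytical_mode: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise DatasetError(
                f"method {self.method_id!r}: category must be one of "
                f"{CATEGORIES}, got {self.category!r}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.category, self.method_id)


@dataclass
class IntegratedDataset:
    """The compiled multi-method replicate-intensity dataset.

    ``measurements`` is a long-format DataFrame with columns
    (method_id, category, metabolite, sample, replicate, intensity);
    intensity is float with NaN for missing.
    """

    methods: list[MethodInfo]
    measurements: pd.DataFrame
    compounds: list[CompoundRecord]
    unresolved: list[str] = field(default_factory=list)
    max_replicates: int = 3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.measurements
        missing_cols = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
        if missing_cols:
            raise DatasetError(f"measurements missing columns {missing_cols}")
        method_keys = {m.key for m in self.methods}
        if len(method_keys) != len(self.methods):
            raise DatasetError("duplicate (category, method_id) in method list")
        compound_ids = {c.canonical_id for c in self.compounds}
        if len(compound_ids) != len(self.compounds):
            raise DatasetError("duplicate canonical_id in compound list")

        if len(df):
            bad_sample = ~df["sample"].isin(SAMPLES)
            if bad_sample.any():
                raise DatasetError(
                    f"invalid sample value(s): "
                    f"{sorted(df.loc[bad_sample, 'sample'].unique())}"
                )
            bad_rep = ~df["replicate"].isin(range(1, self.max_replicates + 1))
            if bad_rep.any():
                raise DatasetError(
                    f"replicate indices outside 1..{self.max_replicates}"
                )
            neg = df["intensity"].lt(0)
            if neg.any():
                raise DatasetError("negative intensity values present")
            keys = df[["category", "method_id", "metabolite", "sample", "replicate"]]
            dup = keys.duplicated()
            if dup.any():
                first = keys[dup].iloc[0]
                raise DatasetError(
                    "duplicate measurement key "
                    f"(category={first['category']!r}, method={first['method_id']!r}, "
                    f"metabolite={first['metabolite']!r}, sample={first['sample']!r}, "
                    f"replicate={first['replicate']})"
                )
            unknown_methods = set(
                zip(df["category"], df["method_id"])
            ) - method_keys
            if unknown_methods:
                raise DatasetError(
                    f"measurements reference unknown methods: "
                    f"{sorted(unknown_methods)}"
                )
            unknown_compounds = set(df["metabolite"]) - compound_ids
            if unknown_compounds:
                raise DatasetError(
                    f"measurements reference unknown compounds: "
                    f"{sorted(unknown_compounds)[:5]}"
                )

    def compound(self, canonical_id: str) -> CompoundRecord:
        for c in self.compounds:
            if c.canonical_id == canonical_id:
                return c
        raise KeyError(canonical_id)

    def methods_in(self, category: str) -> list[MethodInfo]:
        return sorted(
            (m for m in self.methods if m.category == category),
            key=lambda m: m.method_id,
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str], label: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"{label} file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing required column(s) {missing}")
    return df


def read_methods(path: str | Path) -> list[MethodInfo]:
    df = _read_tsv(path, ["method_id", "lab_id", "category"], "method metadata")
    methods = []
    seen: set[tuple[str, str]] = set()
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        info = MethodInfo(
            method_id=row.method_id.strip(),
            lab_id=row.lab_id.strip(),
            category=row.category.strip(),
            platform=getattr(row, "analytical_method", ""),
            analytical_mode=getattr(row, "analytical_mode", ""),
        )
        if info.key in seen:
            raise DatasetError(
                f"{path}: line {lineno}: duplicate method {info.key}"
            )
        seen.add(info.key)
        methods.append(info)
    return methods


def read_compounds(
    path: str | Path, registry: Optional[ClassRegistry] = None
) -> list[CompoundRecord]:
    """Read the compound table; lipid annotations are parsed for hydrophobic
    records whose canonical id follows the shorthand grammar."""
    if registry is None:
        registry = default_registry()
    df = _read_tsv(path, ["canonical_id", "display_name", "category"], "compound")
    compounds = []
    seen: set[str] = set()
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        cid = row.canonical_id.strip()
        if cid in seen:
            raise DatasetError(f"{path}: line {lineno}: duplicate compound {cid!r}")
        seen.add(cid)
        syn_raw = getattr(row, "synonyms", "")
        synonyms = {s.strip() for s in syn_raw.split("|") if s.strip()}
        lipid = None
        if row.category.strip() == "hydrophobic":
            try:
                lipid = parse_lipid_name(cid, registry)
            except NomenclatureError:
                lipid = None
        compounds.append(
            CompoundRecord(
                canonical_id=cid,
                display_name=row.display_name.strip() or cid,
                category=row.category.strip(),
                synonyms=synonyms,
                lipid=lipid,
            )
        )
    return compounds


def _build_synonym_table(
    compounds: Sequence[CompoundRecord],
    extra: Optional[Mapping[str, str]] = None,
) -> dict[str, str]:
    table: dict[str, str] = {}

    def _add(raw: str, canonical: str, source: str) -> None:
        if raw in table and table[raw] != canonical:
            raise DatasetError(
                f"synonym collision ({source}): {raw!r} maps to both "
                f"{table[raw]!r} and {canonical!r}"
            )
        table[raw] = canonical

    for comp in compounds:
        _add(comp.canonical_id, comp.canonical_id, "identity")
        if comp.display_name:
            _add(comp.display_name, comp.canonical_id, "display name")
        for syn in sorted(comp.synonyms):
            _add(syn, comp.canonical_id, "compound table")
    if extra:
        for raw, canonical in extra.items():
            _add(raw, canonical, "synonym file")
    return table


def read_dataset(
    measurements_path: str | Path,
    methods_path: str | Path,
    compounds_path: str | Path,
    synonyms_path: Optional[str | Path] = None,
    registry: Optional[ClassRegistry] = None,
    max_replicates: int = 3,
) -> IntegratedDataset:
    """Read, harmonize and validate a full dataset from TSV files.

    Raw metabolite names in the measurements file are resolved through the
    synonym table plus lipid-shorthand canonicalization; rows whose names
    cannot be resolved are excluded and reported on the returned dataset's
    ``unresolved`` list with a logged warning count.
    """
    if registry is None:
        registry = default_registry()
    methods = read_methods(methods_path)
    compounds = read_compounds(compounds_path, registry)
    extra = read_synonyms_tsv(synonyms_path) if synonyms_path else None
    synonyms = _build_synonym_table(compounds, extra)

    df = _read_tsv(measurements_path, MEASUREMENT_COLUMNS, "measurements")

    # row-level parsing with line numbers (header = line 1)
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        sample = row.sample.strip()
        if sample not in SAMPLES:
            raise DatasetError(
                f"{measurements_path}: line {lineno}: sample must be one of "
                f"{SAMPLES}, got {sample!r}"
            )
        try:
            replicate = int(row.replicate)
        except ValueError as exc:
            raise DatasetError(
                f"{measurements_path}: line {lineno}: bad replicate "
                f"{row.replicate!r}"
            ) from exc
        raw_int = row.intensity.strip()
        if raw_int == "":
            intensity = np.nan
        else:
            try:
                intensity = float(raw_int)
            except ValueError as exc:
                raise DatasetError(
                    f"{measurements_path}: line {lineno}: bad intensity "
                    f"{raw_int!r}"
                ) from exc
            if intensity < 0:
                raise DatasetError(
                    f"{measurements_path}: line {lineno}: negative intensity"
                )
        records.append(
            (
                row.method_id.strip(),
                row.category.strip(),
                row.metabolite.strip(),
                sample,
                replicate,
                intensity,
            )
        )
    parsed = pd.DataFrame(records, columns=MEASUREMENT_COLUMNS)

    mapping, unresolved = harmonize_ids(
        zip(parsed["method_id"], parsed["metabolite"]), synonyms, registry
    )
    # names that canonicalize to ids absent from the compound table stay
    # unresolved rather than silently inventing compounds
    known = {c.canonical_id for c in compounds}
    really_unresolved = set(unresolved)
    for raw, canon in list(mapping.items()):
        if canon not in known:
            really_unresolved.add(raw)
            del mapping[raw]
    if really_unresolved:
        n_rows = int(parsed["metabolite"].isin(really_unresolved).sum())
        logger.warning(
            "excluding %d measurement row(s) with %d unresolved metabolite "
            "name(s): %s",
            n_rows,
            len(really_unresolved),
            sorted(really_unresolved)[:10],
        )
        parsed = parsed[~parsed["metabolite"].isin(really_unresolved)]
    parsed = parsed.assign(metabolite=parsed["metabolite"].map(mapping))
    parsed = parsed.reset_index(drop=True)

    return IntegratedDataset(
        methods=methods,
        measurements=parsed,
        compounds=compounds,
        unresolved=sorted(really_unresolved),
        max_replicates=max_replicates,
    )


# ---------------------------------------------------------------------------
# Writers (stable dialect: tab-delimited, "\n" endings, "." decimal)
# ---------------------------------------------------------------------------


def write_dataset(dataset: IntegratedDataset, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": out_dir / "measurements.tsv",
        "methods": out_dir / "methods.tsv",
        "compounds": out_dir / "compounds.tsv",
    }

    meas = dataset.measurements.loc[:, MEASUREMENT_COLUMNS].copy()
    meas["intensity"] = meas["intensity"].map(
        lambda v: "" if pd.isna(v) else repr(float(v))
    )
    meas.to_csv(paths["measurements"], sep="\t", index=False, lineterminator="\n")

    mrows = [
        {
            "method_id": m.method_id,
            "lab_id": m.lab_id,
            "category": m.category,
            "analytical_method": m.platform,
            "analytical_mode": m.analytical_mode,
        }
        for m in dataset.methods
    ]
    pd.DataFrame(mrows, columns=METHOD_COLUMNS).to_csv(
        paths["methods"], sep="\t", index=False, lineterminator="\n"
    )

    crows = [
        {
            "canonical_id": c.canonical_id,
            "display_name": c.display_name,
            "category": c.category,
            "synonyms": "|".join(sorted(c.synonyms)),
        }
        for c in dataset.compounds
    ]
    pd.DataFrame(crows, columns=COMPOUND_COLUMNS).to_csv(
        paths["compounds"], sep="\t", index=False, lineterminator="\n"
    )
    return paths


# ---------------------------------------------------------------------------
# Detection and coverage
# ---------------------------------------------------------------------------


def replicate_arrays(
    dataset: IntegratedDataset,
) -> dict[tuple[str, str, str], dict[str, np.ndarray]]:
    """Pivot measurements into per-cell replicate vectors.

    Returns {(category, method_id, metabolite): {sample: array of length
    max_replicates with NaN for missing}}.
    """
    out: dict[tuple[str, str, str], dict[str, np.ndarray]] = {}
    n = dataset.max_replicates
    for row in dataset.measurements.itertuples(index=False):
        cell = out.setdefault((row.category, row.method_id, row.metabolite), {})
        vec = cell.get(row.sample)
        if vec is None:
            vec = np.full(n, np.nan)
            cell[row.sample] = vec
        vec[row.replicate - 1] = row.intensity
    return out


def detected(
    dataset: IntegratedDataset,
    method_id: str,
    metabolite: str,
    sample: str,
    min_replicates: int = 2,
) -> bool:
    """True iff >= ``min_replicates`` replicate intensities are present for
    this (method, metabolite, sample) cell.  Zeros count as present."""
    category = dataset.compound(metabolite).category
    df = dataset.measurements
    mask = (
        (df["category"] == category)
        & (df["method_id"] == method_id)
        & (df["metabolite"] == metabolite)
        & (df["sample"] == sample)
    )
    return int(df.loc[mask, "intensity"].notna().sum()) >= min_replicates


@dataclass
class CoverageCounts:
    """Detection bookkeeping: how many metabolites were seen at all, and how
    many were seen in both samples by at least two methods."""

    identified_any: dict[str, int]
    multi_method_both: dict[str, int]

    def as_tuples(self) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        a, m = self.identified_any, self.multi_method_both
        return (
            (a["hydrophilic"], a["hydrophobic"], a["total"]),
            (m["hydrophilic"], m["hydrophobic"], m["total"]),
        )


def coverage_counts(
    dataset: IntegratedDataset, min_replicates: int = 2
) -> CoverageCounts:
    """Count (1) metabolites detected in at least one sample by at least one
    method and (2) metabolites detected in BOTH samples by >= 2 methods,
    per category and in total."""
    arrays = replicate_arrays(dataset)
    compound_category = {c.canonical_id: c.category for c in dataset.compounds}

    any_detected: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    both_methods: dict[tuple[str, str], int] = {}
    for (category, _method, metabolite), samples in arrays.items():
        present = {
            s: int(np.sum(~np.isnan(vec))) >= min_replicates
            for s, vec in samples.items()
        }
        if any(present.values()):
            any_detected[category].add(metabolite)
        if all(present.get(s, False) for s in SAMPLES):
            key = (category, metabolite)
            both_methods[key] = both_methods.get(key, 0) + 1

    multi: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    for (category, metabolite), n_methods in both_methods.items():
        if n_methods >= 2:
            multi[category].add(metabolite)

    # consistency: categories come from the compound table
    for category in CATEGORIES:
        for met in any_detected[category]:
            if compound_category.get(met, category) != category:
                raise DatasetError(
                    f"metabolite {met!r} measured under category {category!r} "
                    f"but registered as {compound_category[met]!r}"
                )

    identified = {c: len(any_detected[c]) for c in CATEGORIES}
    identified["total"] = sum(identified[c] for c in CATEGORIES)
    multi_counts = {c: len(multi[c]) for c in CATEGORIES}
    multi_counts["total"] = sum(multi_counts[c] for c in CATEGORIES)
    return CoverageCounts(identified_any=identified, multi_method_both=multi_counts)
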