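"""Compound-identifier harmonization and lipid shorthand nomenclature.

Multi-laboratory metabolomics datasets rarely integrate cleanly because each
site reports compounds under its own names: "Glutamic acid" vs "Glu",
"pi 18:0/20:2" vs "PI 18:0/20:2", sum-composition vs molecular-species lipid
annotations. This module provides

* a small grammar for glycerophospholipid / sphingolipid / glycerolipid
  shorthand ("PI 18:0/20:2", "PE 34:2", "LPA 16:0 (sn-1)") over a
  configurable class registry,
* canonical writers so that every parseable name has exactly one spelling,
* isomer grouping by sum composition (the unit at which chromatographic
  coelution confuses quantification), and
* a synonym-table driven resolver that maps heterogeneous raw names onto
  canonical identifiers, reporting — never silently dropping — what it
  cannot resolve.

Two annotation levels are distinguished.  A *sum composition* ("PE 34:2")
states only the total acyl carbons and double bonds; a *molecular species*
("PE 16:0/18:2") resolves the individual chains.  Distinct molecular species
sharing a sum composition are structural isomers and collapse into one peak
when a separation method cannot resolve them.  Lysophospholipids carry a
single chain whose glycerol position (sn-1 vs sn-2) distinguishes positional
isomers, written as a trailing "(sn-1)" / "(sn-2)" token.

The class registry (which abbreviations exist, how many chains each class
carries, whether sn annotation is meaningful) is configuration, not code: a
default registry covering 21 common classes ships as package data, and any
registry can be loaded from TSV.  Ether/plasmalogen ("O-"/"P-") shorthand is
outside the supported grammar and is rejected with a clear error.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "LipidParseError",
    "NomenclatureError",
    "ConfigurationError",
    "AnnotationLevel",
    "SnPosition",
    "LipidClassSpec",
    "ClassRegistry",
    "FattyAcylChain",
    "LipidSpecies",
    "CompoundRecord",
    "default_registry",
    "default_fatty_acyl_panel",
    "parse_lipid_name",
    "canonical_name",
    "to_sum_composition",
    "isomer_groups",
    "harmonize_ids",
    "normalize_name",
    "validate_synonyms",
]


class NomenclatureError(ValueError):
    """Base class for naming/validation failures in this module."""


class LipidParseError(NomenclatureError):
    """A name could not be interpreted under the shorthand grammar."""


class ConfigurationError(NomenclatureError):
    """Registry or synonym-table configuration is internally inconsistent."""


class AnnotationLevel(enum.Enum):
    SUM_COMPOSITION = "sum_composition"
    MOLECULAR_SPECIES = "molecular_species"


class SnPosition(enum.Enum):
    SN1 = "sn-1"
    SN2 = "sn-2"


def normalize_name(name: str) -> str:
    """Collapse internal whitespace, strip, and casefold for lenient matching."""
    return " ".join(str(name).split()).casefold()


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LipidClassSpec:
    """One lipid class: its shorthand abbreviation and structural arity."""

    abbreviation: str
    n_chains: int
    supports_sn_annotation: bool = False

    def __post_init__(self) -> None:
        if not self.abbreviation:
            raise ConfigurationError("lipid class abbreviation must be non-empty")
        if self.n_chains < 1:
            raise ConfigurationError(
                f"lipid class {self.abbreviation!r}: n_chains must be >= 1"
            )
        if self.supports_sn_annotation and self.n_chains != 1:
            raise ConfigurationError(
                f"lipid class {self.abbreviation!r}: sn annotation only applies "
                "to single-chain classes"
            )


class ClassRegistry:
    """Lookup of lipid classes by abbreviation (case-insensitive)."""

    def __init__(self, classes: Iterable[LipidClassSpec]):
        self._by_key: dict[str, LipidClassSpec] = {}
        for spec in classes:
            key = spec.abbreviation.casefold()
            if key in self._by_key:
                raise ConfigurationError(
                    f"duplicate lipid class abbreviation {spec.abbreviation!r}"
                )
            self._by_key[key] = spec
        # longest-first so that e.g. "HexCer(NS)" wins over a hypothetical "Hex"
        self._ordered = sorted(
            self._by_key.values(), key=lambda s: -len(s.abbreviation)
        )

    def __iter__(self):
        return iter(self._ordered)

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, abbreviation: str) -> bool:
        return abbreviation.casefold() in self._by_key

    def get(self, abbreviation: str) -> Optional[LipidClassSpec]:
        return self._by_key.get(abbreviation.casefold())

    def match_prefix(self, name: str) -> Optional[tuple[LipidClassSpec, str]]:
        """Return (class, remainder) for the longest class token prefixing *name*.

        The token must be followed by a space or end-of-string so that
        "Cer(NS) 34:1" matches Cer(NS) while "Cereal" matches nothing.
        """
        low = name.casefold()
        for spec in self._ordered:
            abbr = spec.abbreviation.casefold()
            if low.startswith(abbr):
                rest = name[len(abbr):]
                if rest == "" or rest.startswith(" "):
                    return spec, rest.strip()
        return None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClassRegistry":
        """Load a registry from a tab-delimited file.

        Required columns: class_abbreviation, n_chains, supports_sn.
        """
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        if not lines:
            raise ConfigurationError(f"empty registry file: {path}")
        header = lines[0].split("\t")
        required = ["class_abbreviation", "n_chains", "supports_sn"]
        if [h.strip() for h in header[: len(required)]] != required:
            raise ConfigurationError(
                f"registry header must start with {required}, got {header}"
            )
        specs = []
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ConfigurationError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields"
                )
            abbr, n_chains, supports = parts[0].strip(), parts[1], parts[2]
            specs.append(
                LipidClassSpec(
                    abbreviation=abbr,
                    n_chains=int(n_chains),
                    supports_sn_annotation=supports.strip() in ("1", "true", "True"),
                )
            )
        return cls(specs)


def default_registry() -> ClassRegistry:
    """The packaged default registry of 21 lipid classes.

    Covers acylcarnitine (AC), cholesterol ester (ChE), ceramide Cer(NS),
    di-/mono-/tri-acylglycerol (DG/MG/TG), free fatty acid (FA), hexosyl
    ceramide HexCer(NS), the lysophospholipids (LPA/LPC/LPE/LPG/LPI/LPS),
    and the diacyl glycerophospholipids (PA/PC/PE/PG/PI/PS), plus
    sphingomyelin (SM).
    """
    with resources.as_file(
        resources.files("metaconcord").joinpath("data/lipid_classes.tsv")
    ) as p:
        return ClassRegistry.from_tsv(p)


def default_fatty_acyl_panel() -> tuple["FattyAcylChain", ...]:
    """A default panel of 20 common fatty acyl chains (configuration, not
    an authoritative target list; any panel can be supplied as TSV)."""
    with resources.as_file(
        resources.files("metaconcord").joinpath("data/fatty_acyl_panel.tsv")
    ) as p:
        lines = Path(p).read_text(encoding="utf-8").splitlines()
    chains = []
    for line in lines[1:]:
        if not line.strip():
            continue
        c, d = line.split("\t")[:2]
        chains.append(FattyAcylChain(int(c), int(d)))
    return tuple(chains)


# ---------------------------------------------------------------------------
# Species
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class FattyAcylChain:
    """An acyl/sphingoid chain as carbons:double-bonds."""

    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.carbons < 0 or self.double_bonds < 0:
            raise NomenclatureError("chain carbons/double bonds must be >= 0")
        if self.double_bonds > self.carbons:
            raise NomenclatureError(
                f"chain {self.carbons}:{self.double_bonds}: more double bonds "
                "than carbons"
            )

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid annotation at sum-composition or molecular-species level."""

    lipid_class: LipidClassSpec
    chains: tuple[FattyAcylChain, ...]
    sum_carbons: int
    sum_double_bonds: int
    level: AnnotationLevel
    sn_position: Optional[SnPosition] = None

    def __post_init__(self) -> None:
        if self.level is AnnotationLevel.MOLECULAR_SPECIES:
            if not self.chains:
                raise NomenclatureError("molecular species must list its chains")
            if self.sum_carbons != sum(c.carbons for c in self.chains):
                raise NomenclatureError("sum_carbons inconsistent with chains")
            if self.sum_double_bonds != sum(c.double_bonds for c in self.chains):
                raise NomenclatureError("sum_double_bonds inconsistent with chains")
        if self.sn_position is not None:
            if self.lipid_class.n_chains != 1:
                raise NomenclatureError(
                    f"sn annotation invalid for multi-chain class "
                    f"{self.lipid_class.abbreviation}"
                )
            if not self.lipid_class.supports_sn_annotation:
                raise NomenclatureError(
                    f"class {self.lipid_class.abbreviation} does not support "
                    "sn annotation"
                )

    @property
    def sum_composition_key(self) -> str:
        return (
            f"{self.lipid_class.abbreviation} "
            f"{self.sum_carbons}:{self.sum_double_bonds}"
        )


@dataclass
class CompoundRecord:
    """One harmonized compound: canonical id, display name, synonyms,
    hydrophilic/hydrophobic category, and (for lipids) the parsed species."""

    canonical_id: str
    display_name: str
    category: str  # "hydrophilic" | "hydrophobic"
    synonyms: set[str] = field(default_factory=set)
    lipid: Optional[LipidSpecies] = None

    def __post_init__(self) -> None:
        if self.category not in ("hydrophilic", "hydrophobic"):
            raise NomenclatureError(
                f"compound {self.canonical_id!r}: category must be "
                f"'hydrophilic' or 'hydrophobic', got {self.category!r}"
            )


# ---------------------------------------------------------------------------
# Parsing / writing
# ---------------------------------------------------------------------------

_CHAIN_RE = re.compile(r"^(\d+):(\d+)$")
_SN_RE = re.compile(r"\(\s*sn-([12])\s*\)$", re.IGNORECASE)
_ETHER_RE = re.compile(r"(?:^|[ /])([OP])-", re.IGNORECASE)


def parse_lipid_name(
    name: str, registry: Optional[ClassRegistry] = None
) -> LipidSpecies:
    """Parse shorthand like "PI 18:0/20:2", "PE 34:2" or "LPA 16:0 (sn-1)".

    Annotation level is molecular-species iff a "/" chain separator is
    present, or — for single-chain classes — an sn-position token is given
    (a positionally annotated lyso lipid has its one chain resolved).
    """
    if registry is None:
        registry = default_registry()
    norm = " ".join(str(name).split())
    if not norm:
        raise LipidParseError("empty lipid name")

    matched = registry.match_prefix(norm)
    if matched is None:
        token = norm.split(" ")[0]
        raise LipidParseError(
            f"unknown lipid class token {token!r} in {name!r}"
        )
    cls, rest = matched
    if not rest:
        raise LipidParseError(f"{name!r}: missing carbon:double-bond composition")

    ether = _ETHER_RE.search(" " + rest)
    if ether:
        raise LipidParseError(
            f"{name!r}: ether/plasmalogen ({ether.group(1)}-) shorthand is not "
            "supported by this grammar"
        )

    sn_position: Optional[SnPosition] = None
    sn_match = _SN_RE.search(rest)
    if sn_match:
        sn_position = SnPosition.SN1 if sn_match.group(1) == "1" else SnPosition.SN2
        rest = rest[: sn_match.start()].strip()
        if not cls.supports_sn_annotation:
            kind = "multi-chain" if cls.n_chains > 1 else "non-positional"
            raise NomenclatureError(
                f"{name!r}: sn annotation not valid for {kind} class "
                f"{cls.abbreviation}"
            )
    if not rest:
        raise LipidParseError(f"{name!r}: missing composition before sn token")
    if " " in rest:
        raise LipidParseError(f"{name!r}: unexpected token {rest.split(' ', 1)[1]!r}")

    def _chain(token: str) -> FattyAcylChain:
        m = _CHAIN_RE.match(token)
        if not m:
            raise LipidParseError(
                f"{name!r}: chain token {token!r} does not match 'C:D'"
            )
        try:
            return FattyAcylChain(int(m.group(1)), int(m.group(2)))
        except NomenclatureError as exc:
            raise LipidParseError(f"{name!r}: {exc}") from exc

    if "/" in rest:
        chains = tuple(_chain(tok) for tok in rest.split("/"))
        if len(chains) != cls.n_chains:
            raise NomenclatureError(
                f"{name!r}: class {cls.abbreviation} carries {cls.n_chains} "
                f"chain(s), got {len(chains)}"
            )
        return LipidSpecies(
            lipid_class=cls,
            chains=chains,
            sum_carbons=sum(c.carbons for c in chains),
            sum_double_bonds=sum(c.double_bonds for c in chains),
            level=AnnotationLevel.MOLECULAR_SPECIES,
            sn_position=sn_position,
        )

    chain = _chain(rest)
    if sn_position is not None:
        # positional annotation resolves the single chain of a lyso class
        return LipidSpecies(
            lipid_class=cls,
            chains=(chain,),
            sum_carbons=chain.carbons,
            sum_double_bonds=chain.double_bonds,
            level=AnnotationLevel.MOLECULAR_SPECIES,
            sn_position=sn_position,
        )
    return LipidSpecies(
        lipid_class=cls,
        chains=(),
        sum_carbons=chain.carbons,
        sum_double_bonds=chain.double_bonds,
        level=AnnotationLevel.SUM_COMPOSITION,
        sn_position=None,
    )


def canonical_name(species: LipidSpecies) -> str:
    """Deterministic writer: parse(canonical_name(s)) == s for every species
    produced by :func:`parse_lipid_name`."""
    if species.level is AnnotationLevel.MOLECULAR_SPECIES and len(species.chains) > 1:
        body = "/".join(str(c) for c in species.chains)
    elif species.level is AnnotationLevel.MOLECULAR_SPECIES and species.sn_position:
        body = str(species.chains[0])
    else:
        body = f"{species.sum_carbons}:{species.sum_double_bonds}"
    out = f"{species.lipid_class.abbreviation} {body}"
    if species.sn_position is not None:
        out += f" ({species.sn_position.value})"
    return out


def to_sum_composition(species: LipidSpecies) -> LipidSpecies:
    """Collapse a species to its sum composition (idempotent).

    Chains are dropped, total carbons and double bonds are conserved, and
    positional (sn) annotation — a molecular-level detail — is discarded.
    This is the resolution at which coeluting structural isomers merge.
    """
    return LipidSpecies(
        lipid_class=species.lipid_class,
        chains=(),
        sum_carbons=species.sum_carbons,
        sum_double_bonds=species.sum_double_bonds,
        level=AnnotationLevel.SUM_COMPOSITION,
        sn_position=None,
    )


# ---------------------------------------------------------------------------
# Grouping and harmonization
# ---------------------------------------------------------------------------


def isomer_groups(
    compounds: Sequence[CompoundRecord],
    explicit_groups: Optional[Mapping[str, Iterable[str]]] = None,
) -> dict[str, set[str]]:
    """Partition compounds into coelution-relevant isomer groups.

    Lipids group by sum composition (class + total C:D); hydrophilic
    compounds have no structural grammar to infer from, so their groups
    (e.g. hexoses = {glucose, fructose}) must be declared explicitly.
    Every compound lands in exactly one group; singletons are keyed by
    their own canonical id.
    """
    assigned: dict[str, str] = {}
    if explicit_groups:
        for gkey, ids in explicit_groups.items():
            for cid in ids:
                if cid in assigned and assigned[cid] != gkey:
                    raise ConfigurationError(
                        f"compound {cid!r} declared in two isomer groups "
                        f"({assigned[cid]!r} and {gkey!r})"
                    )
                assigned[cid] = gkey

    groups: dict[str, set[str]] = {}
    for comp in compounds:
        if comp.canonical_id in assigned:
            key = assigned[comp.canonical_id]
        elif comp.lipid is not None:
            key = comp.lipid.sum_composition_key
        else:
            key = comp.canonical_id
        groups.setdefault(key, set()).add(comp.canonical_id)
    return groups


def validate_synonyms(synonyms: Mapping[str, str]) -> dict[str, str]:
    """Validate a raw-name -> canonical-id table and return a normalized
    lookup.  Two raw spellings that normalize identically but point at
    different canonical ids are a configuration error (silent ambiguity
    is exactly the failure mode harmonization exists to prevent)."""
    norm_map: dict[str, str] = {}
    for raw, canonical in synonyms.items():
        key = normalize_name(raw)
        if key in norm_map and norm_map[key] != canonical:
            raise ConfigurationError(
                f"synonym collision: {raw!r} normalizes to a key already "
                f"mapped to {norm_map[key]!r}, now {canonical!r}"
            )
        norm_map[key] = canonical
    return norm_map


def read_synonyms_tsv(path: str | Path) -> dict[str, str]:
    """Read a (raw_name, canonical_id) synonym table from TSV."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ConfigurationError(f"empty synonym file: {path}")
    header = [h.strip() for h in lines[0].split("\t")]
    if header[:2] != ["raw_name", "canonical_id"]:
        raise ConfigurationError(
            f"synonym header must start with ['raw_name', 'canonical_id'], "
            f"got {header}"
        )
    table: dict[str, str] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ConfigurationError(
                f"{path}: line {lineno}: expected 2 tab-separated fields"
            )
        raw, canonical = parts[0].strip(), parts[1].strip()
        if raw in table and table[raw] != canonical:
            raise ConfigurationError(
                f"{path}: line {lineno}: raw name {raw!r} mapped twice"
            )
        table[raw] = canonical
    return table


def harmonize_ids(
    raw_names: Iterable[tuple[str, str]],
    synonyms: Mapping[str, str],
    registry: Optional[ClassRegistry] = None,
) -> tuple[dict[str, str], list[str]]:
    """Resolve raw (method_id, raw_name) pairs to canonical ids.

    Resolution order per unique raw name: exact synonym match, then
    case/whitespace-normalized synonym match, then lipid-shorthand
    canonicalization (itself re-resolved through the synonym table).
    Returns (raw_name -> canonical_id mapping, sorted unresolved raw names).
    Unresolved names are reported, never silently dropped.
    """
    if registry is None:
        registry = default_registry()
    norm_map = validate_synonyms(synonyms)

    mapping: dict[str, str] = {}
    unresolved: list[str] = []
    seen: set[str] = set()
    for _method_id, raw in raw_names:
        if raw in seen:
            continue
        seen.add(raw)
        if raw in synonyms:
            mapping[raw] = synonyms[raw]
            continue
        key = normalize_name(raw)
        if key in norm_map:
            mapping[raw] = norm_map[key]
            continue
        try:
            canon = canonical_name(parse_lipid_name(raw, registry))
        except NomenclatureError:
            unresolved.append(raw)
            continue
        mapping[raw] = norm_map.get(normalize_name(canon), canon)
    return mapping, sorted(unresolved)
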