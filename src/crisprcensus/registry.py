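"""The CRISPR-Cas classification registry.

The registry is the machine-readable form of the taxonomy: two classes,
subdivided into types by unique effector modules, and into subtypes by gene
composition.  Each subtype carries the gene-family rules used for locus
classification and completeness calls: families that must all be present
(the effector-module core and signature genes), alternative families of
which one suffices, families whose presence disqualifies the subtype, and
flags saying whether the adaptation module (cas1/cas2) and the CRISPR array
are dispensable.

Two registries ship with the package: the current one ("2025": 2 classes,
7 types, 46 subtypes) and the previous one ("2020": 6 types, 33 subtypes),
plus a legacy-name map so the two can be diffed (e.g. the former single I-F
subtype maps onto I-F1 of the current scheme).
"""

from __future__ import annotations

import json
import os
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

ROLES = {
    "adaptation", "effector-core", "signature-effector", "ancillary",
    "sensor", "signalling-effector", "ring-nuclease", "transposon",
}

#: roles that make a gene family a "core cas" family, i.e. a valid seed for
#: locus assembly (the cas1-cas14 superfamilies and their lettered variants).
CORE_ROLES = {"adaptation", "effector-core", "signature-effector"}


class RegistryError(ValueError):
    """Raised when a registry file violates a structural invariant."""


@dataclass(frozen=True)
class GeneFamily:
    name: str
    role: str
    legacy_names: tuple[str, ...] = ()
    notes: str = ""

    @property
    def is_core(self) -> bool:
        return self.role in CORE_ROLES


@dataclass(frozen=True)
class SubtypeDef:
    id: str
    cas_class: int
    cas_type: str
    required_all: frozenset[str]
    required_any: tuple[frozenset[str], ...] = ()
    forbidden: frozenset[str] = frozenset()
    adaptation_optional: bool = False
    array_optional: bool = False
    variants: tuple[str, ...] = ()
    notes: str = ""

    def signature_families(self, reg: "Registry") -> frozenset[str]:
        """Required families whose role is signature-effector."""
        sig = {f for f in self.required_all
               if reg.families[f].role == "signature-effector"}
        for alt in self.required_any:
            sig |= {f for f in alt
                    if reg.families[f].role == "signature-effector"}
        return frozenset(sig)


@dataclass
class Registry:
    version: str
    families: dict[str, GeneFamily]
    subtypes: dict[str, SubtypeDef]
    legacy_subtype_map: dict[str, str] = field(default_factory=dict)

    # -- convenience queries -------------------------------------------------
    def subtype(self, sid: str) -> SubtypeDef:
        return self.subtypes[sid]

    def crf_families(self) -> list[GeneFamily]:
        """The CARF-domain sensor/ring-nuclease families (Crf nomenclature)."""
        return [f for f in self.families.values() if f.name.startswith("crf")]

    def ring_nucleases(self) -> list[GeneFamily]:
        return [f for f in self.families.values() if f.role == "ring-nuclease"]

    def core_families(self) -> frozenset[str]:
        return frozenset(n for n, f in self.families.items() if f.is_core)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "families": [
                {"name": f.name, "role": f.role,
                 "legacy_names": list(f.legacy_names),
                 **({"notes": f.notes} if f.notes else {})}
                for f in self.families.values()
            ],
            "subtypes": [
                {"id": s.id, "cas_class": s.cas_class, "cas_type": s.cas_type,
                 "required_all": sorted(s.required_all),
                 "required_any": [sorted(a) for a in s.required_any],
                 "forbidden": sorted(s.forbidden),
                 "adaptation_optional": s.adaptation_optional,
                 "array_optional": s.array_optional,
                 "variants": list(s.variants), "notes": s.notes}
                for s in self.subtypes.values()
            ],
            "legacy_subtype_map": dict(self.legacy_subtype_map),
        }


# ---------------------------------------------------------------------------

TYPE_ORDER = ["I", "II", "III", "IV", "V", "VI", "VII"]
CLASS_OF_TYPE = {"I": 1, "III": 1, "IV": 1, "VII": 1, "II": 2, "V": 2, "VI": 2}


def _parse(data: dict) -> Registry:
    if not isinstance(data, dict) or "subtypes" not in data or "families" not in data:
        raise RegistryError("registry file must contain 'families' and 'subtypes'")
    families: dict[str, GeneFamily] = {}
    for f in data["families"]:
        name = f["name"]
        if name in families:
            raise RegistryError(f"duplicate gene family {name!r}")
        if f["role"] not in ROLES:
            raise RegistryError(f"gene family {name!r}: unknown role {f['role']!r}")
        families[name] = GeneFamily(name, f["role"],
                                    tuple(f.get("legacy_names", ())),
                                    f.get("notes", ""))
    subtypes: dict[str, SubtypeDef] = {}
    for s in data["subtypes"]:
        sid = s["id"]
        if sid in subtypes:
            raise RegistryError(f"duplicate subtype id {sid!r}")
        subtypes[sid] = SubtypeDef(
            id=sid, cas_class=int(s["cas_class"]), cas_type=s["cas_type"],
            required_all=frozenset(s["required_all"]),
            required_any=tuple(frozenset(a) for a in s.get("required_any", [])),
            forbidden=frozenset(s.get("forbidden", [])),
            adaptation_optional=bool(s.get("adaptation_optional", False)),
            array_optional=bool(s.get("array_optional", False)),
            variants=tuple(s.get("variants", ())), notes=s.get("notes", ""),
        )
    return Registry(version=str(data.get("version", "")), families=families,
                    subtypes=subtypes,
                    legacy_subtype_map=dict(data.get("legacy_subtype_map", {})))


def validate_registry(reg: Registry) -> list[str]:
    """Return a list of invariant violations (empty iff the registry is valid)."""
    v: list[str] = []
    for s in reg.subtypes.values():
        prefix = s.id.split("-")[0]
        if prefix != s.cas_type:
            v.append(f"subtype {s.id}: id prefix does not match cas_type {s.cas_type}")
        if CLASS_OF_TYPE.get(s.cas_type) != s.cas_class:
            v.append(f"subtype {s.id}: cas_class {s.cas_class} inconsistent with type")
        overlap = s.required_all & s.forbidden
        if overlap:
            v.append(f"subtype {s.id}: families both required and forbidden: "
                     f"{sorted(overlap)}")
        referenced = set(s.required_all) | set(s.forbidden)
        for alt in s.required_any:
            referenced |= set(alt)
        unknown = sorted(g for g in referenced if g not in reg.families)
        for g in unknown:
            v.append(f"subtype {s.id}: unknown gene family {g!r}")
        if not unknown and not s.signature_families(reg):
            v.append(f"subtype {s.id}: no signature-effector family among "
                     "required genes")
    counts = registry_counts(reg)
    if reg.version == "2025":
        if counts.n_subtypes != 46 or counts.n_types != 7 or counts.n_classes != 2:
            v.append(f"2025 registry must have 2 classes / 7 types / 46 subtypes, "
                     f"got {counts.n_classes}/{counts.n_types}/{counts.n_subtypes}")
        expected = {"I": 8, "III": 9, "IV": 3, "VII": 1}
        class1 = sum(counts.per_type.get(t, 0) for t in expected)
        if class1 != 21 or any(counts.per_type.get(t) != n for t, n in expected.items()):
            v.append(f"2025 registry class 1 partition wrong: {counts.per_type}")
    elif reg.version == "2020":
        if counts.n_subtypes != 33 or counts.n_types != 6:
            v.append(f"2020 registry must have 6 types / 33 subtypes, got "
                     f"{counts.n_types}/{counts.n_subtypes}")
    return v


def load_registry(path: str | os.PathLike) -> Registry:
    """Load and validate a registry JSON file."""
    with open(os.fspath(path)) as fh:
        text = fh.read()
    if not text.strip():
        raise RegistryError(f"{path}: empty registry file")
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise RegistryError(f"{path}: not valid JSON ({exc})") from exc
    reg = _parse(data)
    violations = validate_registry(reg)
    if violations:
        raise RegistryError(f"{path}: invalid registry:\n  " + "\n  ".join(violations))
    return reg


def save_registry(reg: Registry, path: str | os.PathLike) -> None:
    from .io import atomic_write_text
    atomic_write_text(path, json.dumps(reg.to_dict(), indent=1) + "\n")


def bundled_registry(version: str = "2025") -> Registry:
    """Load one of the registries shipped with the package ("2025" or "2020")."""
    ref = resources.files("crisprcensus.data") / f"registry_{version}.json"
    with resources.as_file(ref) as path:
        return load_registry(path)


# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegistryCounts:
    n_classes: int
    n_types: int
    n_subtypes: int
    per_type: dict[str, int]
    per_class: dict[int, int]


def registry_counts(reg: Registry) -> RegistryCounts:
    """Enumerate classes, types and subtypes (never cached literals)."""
    per_type = Counter(s.cas_type for s in reg.subtypes.values())
    per_class = Counter(s.cas_class for s in reg.subtypes.values())
    return RegistryCounts(
        n_classes=len(per_class), n_types=len(per_type),
        n_subtypes=len(reg.subtypes),
        per_type={t: per_type[t] for t in TYPE_ORDER if t in per_type},
        per_class=dict(per_class),
    )


def _canonical_ids(reg: Registry, legacy_map: dict[str, str]) -> set[str]:
    return {legacy_map.get(sid, sid) for sid in reg.subtypes}


def diff_registries(new: Registry, old: Registry,
                    legacy_map: dict[str, str] | None = None
                    ) -> tuple[set[str], set[str]]:
    """Subtype ids added in *new* and removed from *old*, after legacy mapping.

    The legacy map (renames like I-F -> I-F1) defaults to the union of the
    maps shipped inside the two registries.
    """
    if legacy_map is None:
        legacy_map = {**old.legacy_subtype_map, **new.legacy_subtype_map}
    new_ids = _canonical_ids(new, legacy_map)
    old_ids = _canonical_ids(old, legacy_map)
    return new_ids - old_ids, old_ids - new_ids
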