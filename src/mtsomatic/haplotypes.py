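"""Hierarchical haplotype nomenclature for hosts and tumours, and donor
haplotype reconstruction.

Host names are ``<haplogroup>_<serial>`` (or ``unassigned``). Tumour names
are ``CTVT_`` (configurable prefix) + clade digit + up to four further
hierarchical levels alternating letter/number (first letter upper-case,
later letters lower-case; five levels total). A non-hierarchical serial
suffix is permitted only once all five levels are occupied: ``1A1a1_2`` is
legal, ``1A_1`` is not.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .classify import ClassifiedVariantSet

__all__ = [
    "HaplogroupDefinition",
    "HaplogroupTree",
    "HaplotypeName",
    "HaplotypeNamer",
    "load_haplogroup_definitions",
    "format_tumour_name",
    "parse_tumour_name",
    "assign_host_haplotype",
    "assign_host_haplotypes",
    "assign_tumour_haplotype",
    "reconstruct_donor_haplotype",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"
DEFAULT_TUMOUR_PREFIX = "CTVT_"
MAX_LEVELS = 5

Key = tuple[int, str, str]
Variant = tuple[int, str]  # (position, "REF>ALT")

# clade digit, then optionally: UPPER letter, digit(s), lower letter, digit(s)
_TUMOUR_LEVELS_RE = re.compile(
    r"^(?P<l1>\d+)(?:(?P<l2>[A-Z])(?:(?P<l3>\d+)(?:(?P<l4>[a-z])(?P<l5>\d+)?)?)?)?$"
)


@dataclass(frozen=True)
class HaplogroupDefinition:
    """A haplogroup with its parent and diagnostic variants."""

    name: str
    parent: str | None
    diagnostic_variants: frozenset[Variant]
    merged_with: tuple[str, ...] = ()  # indistinguishable sibling groups

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("haplogroup name must be non-empty")


class HaplogroupTree:
    """Lookup structure over haplogroup definitions."""

    def __init__(self, definitions: Iterable[HaplogroupDefinition]):
        self.by_name = {d.name: d for d in definitions}
        for d in self.by_name.values():
            if d.parent is not None and d.parent not in self.by_name:
                raise ValueError(f"haplogroup {d.name}: unknown parent {d.parent}")

    def depth(self, name: str) -> int:
        depth = 0
        node = self.by_name[name]
        while node.parent is not None:
            node = self.by_name[node.parent]
            depth += 1
        return depth

    def chain_diagnostics(self, name: str) -> set[Variant]:
        out: set[Variant] = set()
        node = self.by_name[name]
        while True:
            out |= node.diagnostic_variants
            if node.parent is None:
                return out
            node = self.by_name[node.parent]

    def deepest_match(self, variants: set[Variant]) -> tuple[str | None, str | None]:
        """Deepest haplogroup whose full diagnostic chain is present.

        Returns (name, reason); name is None with a reason when nothing
        matches or two incomparable groups match at the same depth.
        """
        matches = [
            name
            for name in self.by_name
            if self.chain_diagnostics(name) <= variants
        ]
        if not matches:
            return None, "no haplogroup match"
        best_depth = max(self.depth(m) for m in matches)
        deepest = sorted(m for m in matches if self.depth(m) == best_depth)
        if len(deepest) == 1:
            return deepest[0], None
        # multiple deepest matches: legal only when they are declared
        # indistinguishable (merged) with each other, e.g. A1c/A1e
        families = {frozenset((m, *self.by_name[m].merged_with)) for m in deepest}
        if len(families) == 1 and set(deepest) <= next(iter(families)):
            return "/".join(deepest), None
        return None, f"conflicting diagnostics: {'/'.join(deepest)}"


def load_haplogroup_definitions(path: str | Path) -> HaplogroupTree:
    """Load haplogroup definitions from YAML.

    The file is a list of entries::

        - name: A1
          parent: A
          variants: ["200:C>T"]
          merged_with: []   # optional: indistinguishable sibling groups

    An illustrative set ships with the package
    (``mtsomatic/data/example_haplogroups.yaml``); study-specific diagnostic
    tables are external inputs.
    """
    with open(path) as fh:
        entries = yaml.safe_load(fh) or []
    definitions = []
    for entry in entries:
        variants = frozenset(
            (int(v.split(":")[0]), v.split(":")[1]) for v in entry.get("variants", [])
        )
        definitions.append(
            HaplogroupDefinition(
                name=str(entry["name"]),
                parent=entry.get("parent"),
                diagnostic_variants=variants,
                merged_with=tuple(entry.get("merged_with", ())),
            )
        )
    return HaplogroupTree(definitions)


@dataclass(frozen=True)
class HaplotypeName:
    """A validated haplotype name."""

    text: str
    haplogroup: str
    serial: int | None = None
    reason: str | None = None  # set when unassigned

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


class HaplotypeNamer:
    """Assigns stable serial numbers to distinct variant sets per group."""

    def __init__(self) -> None:
        self._serials: dict[str, dict[frozenset, int]] = {}

    def serial_for(self, group: str, variants: Iterable[Variant]) -> int:
        seen = self._serials.setdefault(group, {})
        key = frozenset(variants)
        if key not in seen:
            seen[key] = len(seen) + 1
        return seen[key]


def parse_tumour_name(levels: str) -> list[str]:
    """Split a hierarchical level string like ``1A1a1`` into its levels."""
    m = _TUMOUR_LEVELS_RE.match(levels)
    if m is None:
        raise ValueError(f"malformed tumour hierarchy levels: {levels!r}")
    return [g for g in m.groups() if g is not None]


def format_tumour_name(
    clade: int,
    levels: Sequence[str] = (),
    serial: int | None = None,
    prefix: str = DEFAULT_TUMOUR_PREFIX,
) -> HaplotypeName:
    """Build and validate a tumour haplotype name.

    ``levels`` are the hierarchy levels below the clade digit (at most
    four). A serial suffix requires all five levels to be occupied.
    """
    if clade < 1:
        raise ValueError("clade must be a positive integer")
    parts = [str(clade), *map(str, levels)]
    if len(parts) > MAX_LEVELS:
        raise ValueError(f"more than {MAX_LEVELS} hierarchical levels: {parts}")
    body = "".join(parts)
    parsed = parse_tumour_name(body)
    if parsed != parts:
        raise ValueError(f"levels {parts} violate the alternation rules")
    if serial is not None:
        if len(parts) < MAX_LEVELS:
            raise ValueError(
                f"serial suffix requires all {MAX_LEVELS} levels "
                f"(got {len(parts)}: {body!r}); e.g. '1A_1' does not exist"
            )
        if serial < 1:
            raise ValueError("serial must be >= 1")
        text = f"{prefix}{body}_{serial}"
    else:
        text = f"{prefix}{body}"
    return HaplotypeName(text=text, haplogroup=f"{prefix}{body}", serial=serial)


def assign_host_haplotype(
    variants: Iterable[Variant],
    tree: HaplogroupTree,
    namer: HaplotypeNamer,
) -> HaplotypeName:
    """Name one host haplotype: deepest matching haplogroup + serial."""
    variant_set = set(variants)
    group, reason = tree.deepest_match(variant_set)
    if group is None:
        return HaplotypeName(text=UNASSIGNED, haplogroup=UNASSIGNED, reason=reason)
    serial = namer.serial_for(group, variant_set)
    return HaplotypeName(text=f"{group}_{serial}", haplogroup=group, serial=serial)


def assign_host_haplotypes(
    variants_by_sample: Mapping[str, Iterable[Variant]],
    tree: HaplogroupTree,
) -> dict[str, HaplotypeName]:
    """Name all hosts; samples are processed in canonical (sorted) order so
    serial assignment does not depend on input order."""
    namer = HaplotypeNamer()
    return {
        sample: assign_host_haplotype(variants_by_sample[sample], tree, namer)
        for sample in sorted(variants_by_sample)
    }


def assign_tumour_haplotype(
    variants: Iterable[Variant],
    clade: int,
    hierarchy: HaplogroupTree | None,
    namer: HaplotypeNamer | None = None,
    prefix: str = DEFAULT_TUMOUR_PREFIX,
) -> HaplotypeName:
    """Name a tumour haplotype from the clade hierarchy.

    ``hierarchy`` holds haplogroups named by their level string (``1A``,
    ``1A1``, ...); with no hierarchy (or no match) the clade root name is
    used. Serial suffixes are drawn from ``namer`` only for groups at the
    maximum hierarchical depth.
    """
    if not isinstance(clade, int) or clade < 1:
        raise ValueError("clade must be a positive integer")
    variant_set = set(variants)
    group = None
    if hierarchy is not None:
        group, _ = hierarchy.deepest_match(variant_set)
    if group is None:
        return format_tumour_name(clade, (), None, prefix)
    levels = parse_tumour_name(group)
    if str(clade) != levels[0]:
        raise ValueError(f"hierarchy group {group} does not belong to clade {clade}")
    serial = None
    if len(levels) == MAX_LEVELS and namer is not None:
        serial = namer.serial_for(group, variant_set)
    return format_tumour_name(clade, levels[1:], serial, prefix)


def reconstruct_donor_haplotype(
    classified: ClassifiedVariantSet, clade: object
) -> set[Key]:
    """Donor haplotype = clade-defining germline + potential-somatic."""
    if clade not in classified.clade_defining:
        raise ValueError(f"unknown or empty clade {clade!r}")
    return set(classified.clade_defining[clade]) | set(
        classified.potential_somatic[clade]
    )
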