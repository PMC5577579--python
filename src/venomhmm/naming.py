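"""The three-level SC/SN/VP classifier nomenclature.

Classifier names follow ``XX_nn_mm``: a two-letter sequence-type code
(``SC`` short cationic peptides, ``SN`` spider neurotoxins, ``VP`` venom
proteins), a two-digit family number (level 2), and a two-digit group
number inside the family (level 3). Level-3 index ``00`` denotes the
global family classifier that is expected to match every member of the
family; a win by a ``00`` model with no more specific sibling match marks
a candidate for designing a new level-3 group.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from . import io_formats

_NAME_RE = re.compile(r"^(SC|SN|VP)_(\d{2})_(\d{2})$")
TYPE_CODES = ("SC", "SN", "VP")


@dataclass(frozen=True, order=True)
class ClassifierName:
    type_code: str
    level2: int
    level3: int

    def __post_init__(self) -> None:
        if self.type_code not in TYPE_CODES:
            raise ValueError(f"unknown type code: {self.type_code!r}")
        for lv in (self.level2, self.level3):
            if not 0 <= lv <= 99:
                raise ValueError(
                    f"level value {lv} outside the two-digit range 0-99"
                )

    def render(self) -> str:
        return f"{self.type_code}_{self.level2:02d}_{self.level3:02d}"

    @property
    def is_global(self) -> bool:
        """Level-3 index 00: the family-wide classifier."""
        return self.level3 == 0

    @property
    def family(self) -> str:
        return f"{self.type_code}_{self.level2:02d}"


def parse_name(text: str) -> ClassifierName:
    """Parse ``XX_nn_mm``, naming the offending part on failure."""
    m = _NAME_RE.match(text)
    if not m:
        parts = text.split("_")
        if len(parts) != 3:
            raise ValueError(
                f"{text!r}: expected three underscore-separated parts"
            )
        if parts[0] not in TYPE_CODES:
            raise ValueError(
                f"{text!r}: type code {parts[0]!r} is not one of SC/SN/VP"
            )
        for label, part in (("family", parts[1]), ("group", parts[2])):
            if not re.fullmatch(r"\d{2}", part):
                raise ValueError(
                    f"{text!r}: {label} part {part!r} is not two digits"
                )
        raise ValueError(f"{text!r}: malformed classifier name")
    return ClassifierName(m.group(1), int(m.group(2)), int(m.group(3)))


def expand_range(text: str) -> list[ClassifierName]:
    """Expand a single name or an inclusive ``A to B`` level-3 span."""
    text = text.strip()
    if " to " in text:
        first_text, last_text = (t.strip() for t in text.split(" to ", 1))
        first, last = parse_name(first_text), parse_name(last_text)
        if (first.type_code, first.level2) != (last.type_code, last.level2):
            raise ValueError(
                f"range {text!r} spans different families"
            )
        if last.level3 < first.level3:
            raise ValueError(f"range {text!r} runs backwards")
        return [
            ClassifierName(first.type_code, first.level2, lv)
            for lv in range(first.level3, last.level3 + 1)
        ]
    return [parse_name(text)]


@dataclass
class RegistryEntry:
    desc: str
    interpro_ids: list[str]
    pfam_ids: list[str]


@dataclass
class Registry:
    """Mapping from classifier name to its legacy annotation and signatures."""

    entries: dict[ClassifierName, RegistryEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, name: str | ClassifierName) -> RegistryEntry | None:
        if isinstance(name, str):
            name = parse_name(name)
        return self.entries.get(name)

    def families(self) -> dict[str, list[ClassifierName]]:
        out: dict[str, list[ClassifierName]] = {}
        for name in self.entries:
            out.setdefault(name.family, []).append(name)
        for names in out.values():
            names.sort()
        return out


def load_registry_from_table3() -> Registry:
    """Build the registry from the packaged classifier table.

    Each classifier inherits the legacy ToxProt family annotation of its
    table row as its description (the DESC line of the written profile),
    easing the transition from the historical names.
    """
    entries: dict[ClassifierName, RegistryEntry] = {}
    for row in io_formats.load_fixture_table3():
        for name in expand_range(row.name_range):
            if name in entries:
                raise ValueError(
                    f"duplicate classifier {name.render()} in registry table"
                )
            if name.type_code != row.toxin_type:
                raise ValueError(
                    f"{name.render()} listed under type {row.toxin_type}"
                )
            entries[name] = RegistryEntry(
                desc=row.legacy_annotation,
                interpro_ids=list(row.interpro_ids),
                pfam_ids=list(row.pfam_ids),
            )
    return Registry(entries=entries)


def count_by_type(registry: Registry) -> dict[str, int]:
    counts = {code: 0 for code in TYPE_CODES}
    for name in registry.entries:
        counts[name.type_code] += 1
    return counts


_ALT_RE = re.compile(r"\((\d+)-(\d+)#([^#()]+)#(-?[\d.]+)\)")


@dataclass
class HierarchyReport:
    """Advisory output of :func:`hierarchy_check` (never mutates anything)."""

    new_subgroup_candidates: list[tuple[str, str]]  # (seq_id, winner)
    undivided_families: list[str]

    def to_tsv(self) -> str:
        lines = ["kind\tsubject\tdetail"]
        for seq_id, winner in self.new_subgroup_candidates:
            lines.append(f"new-subgroup-candidate\t{seq_id}\t{winner}")
        for family in self.undivided_families:
            lines.append(f"undivided-family\t{family}\t")
        return "\n".join(lines) + "\n"


def hierarchy_check(registry: Registry, classification_rows) -> HierarchyReport:
    """Flag classification results suggesting registry evolution.

    A sequence won by a global ``xx_nn_00`` model with no level-3 sibling
    among its alternative matches is a candidate for a new, more specific
    group. Families represented only by their ``00`` model are reported as
    undivided.
    """
    candidates: list[tuple[str, str]] = []
    for row in classification_rows:
        if not row.classifier_name:
            continue
        try:
            winner = parse_name(row.classifier_name)
        except ValueError:
            continue  # winner outside the SC/SN/VP registry naming
        if not winner.is_global:
            continue
        sibling_matched = False
        for m in _ALT_RE.finditer(row.matches_position or ""):
            try:
                alt = parse_name(m.group(3))
            except ValueError:
                continue
            if alt.family == winner.family and not alt.is_global:
                sibling_matched = True
                break
        if not sibling_matched:
            candidates.append((row.sequence_id, winner.render()))

    undivided = [
        family for family, names in sorted(registry.families().items())
        if len(names) == 1 and names[0].is_global
    ]
    return HierarchyReport(
        new_subgroup_candidates=candidates,
        undivided_families=undivided,
    )


def registry_to_tsv(registry: Registry) -> str:
    lines = ["name\tdesc\tinterpro\tpfam"]
    for name in sorted(registry.entries):
        e = registry.entries[name]
        lines.append("\t".join([
            name.render(), e.desc,
            ";".join(e.interpro_ids), ";".join(e.pfam_ids),
        ]))
    return "\n".join(lines) + "\n"
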