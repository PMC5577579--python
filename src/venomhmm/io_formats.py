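"""Readers and writers for the formats the classification tool touches.

FASTA and alignment parsing is delegated to Biopython; profile databases
use a plain-text subset of the HMMER3 ASCII format (one concatenated file,
``//``-terminated entries, probabilities stored as negative natural logs).
Two reference tables ship with the package: the InterPro/Pfam signature
table describing the legacy ToxProt annotation of 1036 spider toxins, and
the SC/SN/VP classifier registry with legacy family descriptions.
"""

from __future__ import annotations

import hashlib
import io
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .profile_hmm import AMBIGUOUS_RESIDUES, AMINO_ACIDS, ProfileHMM

_VALID_RESIDUES = set(AMINO_ACIDS) | set(AMBIGUOUS_RESIDUES)


@dataclass
class SequenceRecord:
    """One protein sequence.

    ``seq_id`` is the FASTA header between ``>`` and the first whitespace
    character (the same truncation applied by homology-search tools, which
    is why identifiers must not contain spaces); ``description`` is the
    remainder of the header.
    """

    seq_id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.seq_id or any(c.isspace() for c in self.seq_id):
            raise ValueError(f"invalid sequence id: {self.seq_id!r}")
        if not self.residues:
            raise ValueError(f"{self.seq_id}: empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in _VALID_RESIDUES:
                raise ValueError(
                    f"{self.seq_id}: invalid residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Msa:
    """A multiple sequence alignment with '-' as the gap character."""

    name: str
    rows: list[tuple[str, str]]
    width: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"{self.name}: alignment has no rows")
        widths = {len(aligned) for _sid, aligned in self.rows}
        if len(widths) != 1:
            bad = [sid for sid, aligned in self.rows
                   if len(aligned) != len(self.rows[0][1])]
            raise ValueError(
                f"{self.name}: rows have unequal widths (offending: {bad})"
            )
        ids = [sid for sid, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.name}: duplicate row identifiers")
        self.width = widths.pop()


@dataclass
class FixtureTable1Row:
    """One row of the legacy InterPro/Pfam signature table."""

    interpro_combo: list[str]
    pfam_ids: list[str]
    tpl1_families: list[tuple[str, int | None]]
    total_count: int


@dataclass
class FixtureTable3Row:
    """One row of the SC/SN/VP classifier registry table."""

    toxin_type: str
    name_range: str
    legacy_annotation: str
    interpro_ids: list[str]
    pfam_ids: list[str]


def _open_text(path_or_stream):
    if hasattr(path_or_stream, "read"):
        return path_or_stream, False
    return open(path_or_stream, "r", encoding="utf-8"), True


def read_fasta(path_or_stream) -> list[SequenceRecord]:
    """Parse FASTA records, truncating ids at the first space.

    Residues are uppercased; duplicate identifiers and non-amino-acid
    characters raise ``ValueError``.
    """
    handle, owned = _open_text(path_or_stream)
    try:
        records = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            sr = SequenceRecord(
                seq_id=rec.id,
                description=desc,
                residues=str(rec.seq).upper(),
            )
            if sr.seq_id in seen:
                raise ValueError(f"duplicate sequence id: {sr.seq_id}")
            seen.add(sr.seq_id)
            records.append(sr)
    finally:
        if owned:
            handle.close()
    if not records:
        raise ValueError("no FASTA records found")
    return records


def write_fasta(records: list[SequenceRecord], path_or_stream,
                line_width: int = 60) -> None:
    handle, owned = (path_or_stream, False) if hasattr(
        path_or_stream, "write") else (
        open(path_or_stream, "w", encoding="utf-8"), True)
    try:
        for rec in records:
            header = rec.seq_id
            if rec.description:
                header += " " + rec.description
            handle.write(f">{header}\n")
            for i in range(0, len(rec.residues), line_width):
                handle.write(rec.residues[i:i + line_width] + "\n")
    finally:
        if owned:
            handle.close()


def read_msa(path_or_stream, dialect: str = "afa",
             name: str = "msa") -> Msa:
    """Read an alignment in aligned-FASTA (``afa``) or ``stockholm``.

    ``.`` gaps are normalised to ``-``; ragged input raises with the
    offending row named; Stockholm annotation lines are ignored.
    """
    handle, owned = _open_text(path_or_stream)
    try:
        text = handle.read()
    finally:
        if owned:
            handle.close()

    rows: list[tuple[str, str]] = []
    if dialect in ("afa", "fasta", "aligned-fasta"):
        for rec in SeqIO.parse(io.StringIO(text), "fasta"):
            rows.append((rec.id, str(rec.seq).upper().replace(".", "-")))
    elif dialect == "stockholm":
        # Parsed by hand so ragged rows can be reported by name; Stockholm
        # is line-oriented: "#..." annotations, "name sequence" data rows,
        # "//" terminator. Sequence rows may be split across blocks.
        collected: dict[str, str] = {}
        order: list[str] = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line == "//":
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed Stockholm line: {line!r}")
            sid, chunk = parts
            if sid not in collected:
                collected[sid] = ""
                order.append(sid)
            collected[sid] += chunk.upper().replace(".", "-")
        rows = [(sid, collected[sid]) for sid in order]
    else:
        raise ValueError(f"unknown alignment dialect: {dialect!r}")
    if not rows:
        raise ValueError("no alignment rows found")
    return Msa(name=name, rows=rows)


# --------------------------------------------------------------------------
# HMMER3 ASCII profile databases (subset)

_HMM_HEADER = "HMMER3/f [venomhmm profile format]"


def _fmt(p: float) -> str:
    """Probability -> negative natural log with 5 decimals; '*' for zero."""
    if p <= 0.0:
        return "*"
    return f"{-math.log(p):.5f}"


def _parse_prob(tok: str) -> float:
    if tok == "*":
        return 0.0
    return math.exp(-float(tok))


def write_hmm_db(models: list[ProfileHMM], path_or_stream) -> None:
    """Write models as one concatenated HMMER3-style ASCII file.

    Model names must be unique and contain no whitespace (tabular outputs
    downstream are whitespace-delimited, so a space in a profile name
    would corrupt every report referring to it).
    """
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        raise ValueError("duplicate model names in database")
    for nm in names:
        if not nm or any(c.isspace() for c in nm):
            raise ValueError(
                f"profile name {nm!r} is empty or contains whitespace"
            )
    handle, owned = (path_or_stream, False) if hasattr(
        path_or_stream, "write") else (
        open(path_or_stream, "w", encoding="utf-8"), True)
    try:
        for m in models:
            handle.write(_HMM_HEADER + "\n")
            handle.write(f"NAME  {m.name}\n")
            if m.desc:
                handle.write(f"DESC  {m.desc}\n")
            handle.write(f"LENG  {m.length}\n")
            handle.write("ALPH  amino\n")
            handle.write("HMM  " + "  ".join(AMINO_ACIDS) + "\n")
            handle.write("     m->m m->i m->d i->m i->i d->m d->d\n")
            handle.write("  BACKG  " +
                         " ".join(_fmt(p) for p in m.background) + "\n")
            handle.write("  " + " ".join(
                _fmt(p) for p in m.insert_emissions[0]) + "\n")
            handle.write("  " + " ".join(
                _fmt(p) for p in m.transitions[0]) + "\n")
            for k in range(1, m.length + 1):
                handle.write(f"  {k} " + " ".join(
                    _fmt(p) for p in m.match_emissions[k - 1]) + "\n")
                handle.write("  " + " ".join(
                    _fmt(p) for p in m.insert_emissions[k]) + "\n")
                handle.write("  " + " ".join(
                    _fmt(p) for p in m.transitions[k]) + "\n")
            handle.write("//\n")
    finally:
        if owned:
            handle.close()


def read_hmm_db(path_or_stream) -> list[ProfileHMM]:
    """Read a concatenated profile database written by :func:`write_hmm_db`.

    Unrecognised header lines are ignored; a model without its ``//``
    terminator raises a truncation error.
    """
    handle, owned = _open_text(path_or_stream)
    try:
        lines = handle.read().splitlines()
    finally:
        if owned:
            handle.close()

    models: list[ProfileHMM] = []
    i = 0
    n = len(lines)
    while i < n:
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith("HMMER3"):
            raise ValueError(f"expected HMMER3 header, got: {lines[i]!r}")
        i += 1
        name = desc = None
        leng = None
        while i < n and not lines[i].lstrip().startswith("HMM "):
            parts = lines[i].split(None, 1)
            if parts:
                key = parts[0]
                val = parts[1].strip() if len(parts) > 1 else ""
                if key == "NAME":
                    name = val
                elif key == "DESC":
                    desc = val
                elif key == "LENG":
                    leng = int(val)
                elif key == "ALPH":
                    if val.lower() != "amino":
                        raise ValueError(f"unsupported alphabet: {val!r}")
            i += 1
        if i >= n or name is None or leng is None:
            raise ValueError("truncated profile entry (missing HMM block)")
        i += 2  # skip the two HMM header lines
        background = np.full(20, 0.05)
        if i < n and lines[i].split()[:1] == ["BACKG"]:
            background = np.array(
                [_parse_prob(t) for t in lines[i].split()[1:21]])
            i += 1
        insert0 = np.array([_parse_prob(t) for t in lines[i].split()])
        trans0 = np.array([_parse_prob(t) for t in lines[i + 1].split()])
        i += 2
        match_em = np.zeros((leng, 20))
        insert_em = np.zeros((leng + 1, 20))
        trans = np.zeros((leng + 1, 7))
        insert_em[0] = insert0
        trans[0] = trans0
        for k in range(1, leng + 1):
            if i + 2 > n:
                raise ValueError(f"{name}: truncated profile body")
            mtoks = lines[i].split()
            if int(mtoks[0]) != k:
                raise ValueError(f"{name}: node numbering broken at {k}")
            match_em[k - 1] = [_parse_prob(t) for t in mtoks[1:21]]
            insert_em[k] = [_parse_prob(t) for t in lines[i + 1].split()]
            trans[k] = [_parse_prob(t) for t in lines[i + 2].split()]
            i += 3
        if i >= n or lines[i].strip() != "//":
            raise ValueError(f"{name}: missing '//' terminator (truncated)")
        i += 1
        models.append(ProfileHMM(
            name=name, desc=desc or "", length=leng,
            match_emissions=match_em, insert_emissions=insert_em,
            transitions=trans, background=background,
        ))
    if not models:
        raise ValueError("no profiles found in database")
    return models


# --------------------------------------------------------------------------
# hmmsearch --domtblout style table (winners only)

_HSOUT_HEADER = (
    "# target_name accession tlen query_name accession qlen "
    "full_E-value full_score full_bias dom_n dom_of c-Evalue i-Evalue "
    "dom_score dom_bias hmm_from hmm_to ali_from ali_to env_from env_to "
    "acc description"
)


def write_hsout(rows, path_or_stream) -> None:
    """Write winners as a space-delimited, domtblout-style table.

    The best-domain bit score sits in column 14 of each data line, the
    column classification pipelines conventionally read; unmatched
    sequences and alternative matches are omitted.
    """
    handle, owned = (path_or_stream, False) if hasattr(
        path_or_stream, "write") else (
        open(path_or_stream, "w", encoding="utf-8"), True)
    try:
        handle.write(_HSOUT_HEADER + "\n")
        for row in rows:
            if not row.classifier_name:
                continue
            score = f"{row.bit_score:.1f}"
            desc = row.classifier_desc or "-"
            fields = [
                row.sequence_id, "-", "-", row.classifier_name, "-", "-",
                "-", score, "0.0", "1", "1", "-", "-",
                score, "0.0", "-", "-",
                str(row.ali_from), str(row.ali_to),
                str(row.ali_from), str(row.ali_to), "-", desc,
            ]
            handle.write(" ".join(fields) + "\n")
    finally:
        if owned:
            handle.close()


# --------------------------------------------------------------------------
# Packaged reference tables

_TABLE1_RESOURCE = "interpro_pfam_families.tsv"
_TABLE3_RESOURCE = "classifier_registry.tsv"
_TABLE1_SHA256 = (
    "9f1093cb2bbeb55678b705e348b5b29dc25a330dc176bba0c3daf161f5657a1e"
)
_TABLE3_SHA256 = (
    "453c0c1efcec50b10d5bf0b6873e9545a40e25e82c15535db3c51981d70a511e"
)


def _read_resource(name: str, sha256: str) -> str:
    data = (resources.files("venomhmm") / "data" / name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != sha256:
        raise ValueError(
            f"packaged table {name} failed its integrity check "
            f"(sha256 {digest} != {sha256})"
        )
    return data.decode("utf-8")


def _split_ids(cell: str) -> list[str]:
    return [t.strip() for t in cell.split(";") if t.strip()]


def load_fixture_table1() -> list[FixtureTable1Row]:
    """The legacy InterPro/Pfam signature table (1036 classified toxins)."""
    text = _read_resource(_TABLE1_RESOURCE, _TABLE1_SHA256)
    lines = text.splitlines()
    rows = []
    for line in lines[1:]:
        cells = line.split("\t")
        cells += [""] * (4 - len(cells))
        interpro, pfam, families_cell, total = cells[:4]
        families: list[tuple[str, int | None]] = []
        if families_cell:
            parts = families_cell.split("|")
            for part in parts:
                if "=" in part:
                    fam, cnt = part.rsplit("=", 1)
                    families.append((fam, int(cnt)))
                else:
                    families.append((part, None))
        row = FixtureTable1Row(
            interpro_combo=_split_ids(interpro),
            pfam_ids=_split_ids(pfam),
            tpl1_families=families,
            total_count=int(total),
        )
        per_family = [c for _f, c in row.tpl1_families if c is not None]
        if per_family and sum(per_family) != row.total_count:
            raise ValueError(
                f"table row {interpro}: family counts {per_family} do not "
                f"sum to {row.total_count}"
            )
        rows.append(row)
    return rows


def load_fixture_table3() -> list[FixtureTable3Row]:
    """The SC/SN/VP classifier registry table (219 profile names)."""
    text = _read_resource(_TABLE3_RESOURCE, _TABLE3_SHA256)
    lines = text.splitlines()
    rows = []
    for line in lines[1:]:
        cells = line.split("\t")
        cells += [""] * (5 - len(cells))
        toxin_type, name_range, legacy, interpro, pfam = cells[:5]
        rows.append(FixtureTable3Row(
            toxin_type=toxin_type,
            name_range=name_range,
            legacy_annotation=legacy,
            interpro_ids=_split_ids(interpro),
            pfam_ids=_split_ids(pfam),
        ))
    return rows
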