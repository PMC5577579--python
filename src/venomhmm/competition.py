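"""Best-classifier competition between profile HMMs.

Closely related profile HMMs routinely all match the same peptide, so a
plain database search reports many overlapping hits per sequence. The
competition engine scores every model against every query, keeps the hits
with a positive best-domain bit score, and reports for each sequence only
the winning classifier (highest bit score; ties broken by the
lexicographically smallest model name, a documented arbitrary rule).
Reports can include the matched region, the winner's description line,
and a compact encoding of all alternative matches.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass, field

from .io_formats import SequenceRecord
from .profile_hmm import DomainHit, ProfileHMM, viterbi_best_domain


@dataclass
class CompeteOptions:
    """Report options; every flag defaults to off."""

    show_desc: bool = False       # -d/--desc
    show_altpred: bool = False    # --altpred
    show_allseq: bool = False     # --allseq
    show_pepreg: bool = False     # --pepreg
    out_path: str | None = None
    hsout_path: str | None = None
    htmout_path: str | None = None


@dataclass
class ClassificationRow:
    """One line of the competition report."""

    sequence_id: str
    classifier_name: str = ""
    ali_from: int | None = None
    ali_to: int | None = None
    bit_score: float | None = None
    target_region: str = ""
    classifier_desc: str = ""
    matches_count: int = 0
    matches_position: str = ""

    @property
    def matched(self) -> bool:
        return bool(self.classifier_name)


def encode_alternatives(hits: list[DomainHit]) -> tuple[int, str]:
    """Encode hits as ``(ali_from-ali_to#classifier_name#bit_score)``
    entries, best score first (name breaks ties), scores to 1 decimal."""
    ordered = sorted(hits, key=lambda h: (-h.bit_score, h.model_name))
    text = "".join(
        f"({h.ali_from}-{h.ali_to}#{h.model_name}#{h.bit_score:.1f})"
        for h in ordered
    )
    return len(ordered), text


def compete(models: list[ProfileHMM], seqs: list[SequenceRecord],
            opts: CompeteOptions | None = None) -> list[ClassificationRow]:
    """Score every model against every sequence and keep the winners.

    A model "matches" when its best-domain bit score is positive. Rows
    follow the input sequence order; the result is independent of the
    order of ``models``. Sequences without any match are omitted unless
    ``opts.show_allseq`` is set, in which case they appear with empty
    classifier fields.
    """
    opts = opts or CompeteOptions()
    if not models:
        raise ValueError("at least one profile HMM is required")
    if not seqs:
        raise ValueError("at least one query sequence is required")
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate model names: {dupes}")

    rows: list[ClassificationRow] = []
    for seq in seqs:
        hits = []
        for model in models:
            hit = viterbi_best_domain(model, seq)
            if hit is not None:
                hits.append(hit)
        if not hits:
            if opts.show_allseq:
                rows.append(ClassificationRow(sequence_id=seq.seq_id))
            continue
        hits.sort(key=lambda h: (-h.bit_score, h.model_name))
        winner = hits[0]
        count, encoded = encode_alternatives(hits)
        desc = ""
        if opts.show_desc:
            by_name = {m.name: m for m in models}
            desc = by_name[winner.model_name].desc
        region = ""
        if opts.show_pepreg:
            region = seq.residues[winner.ali_from - 1:winner.ali_to]
        rows.append(ClassificationRow(
            sequence_id=seq.seq_id,
            classifier_name=winner.model_name,
            ali_from=winner.ali_from,
            ali_to=winner.ali_to,
            bit_score=winner.bit_score,
            target_region=region,
            classifier_desc=desc,
            matches_count=count,
            matches_position=encoded,
        ))
    return rows


def _columns(opts: CompeteOptions) -> list[str]:
    cols = ["sequence_id", "classifier_name", "ali_from", "ali_to"]
    if opts.show_pepreg:
        cols.append("target_region")
    if opts.show_desc:
        cols.append("classifier_desc")
    if opts.show_altpred:
        cols += ["matches_count", "matches_position"]
    return cols


def _cell(row: ClassificationRow, col: str) -> str:
    value = getattr(row, col)
    if not row.matched and col != "sequence_id":
        return ""
    if value is None:
        return ""
    return str(value)


def render_tsv(rows: list[ClassificationRow],
               opts: CompeteOptions | None = None) -> str:
    """Tab-separated report; optional columns appear only when their flag
    is set."""
    opts = opts or CompeteOptions()
    cols = _columns(opts)
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append("\t".join(_cell(row, c) for c in cols))
    return "\n".join(lines) + "\n"


def render_html(rows: list[ClassificationRow],
                opts: CompeteOptions | None = None) -> str:
    """HTML table mirroring the TSV report cell for cell."""
    opts = opts or CompeteOptions()
    cols = _columns(opts)
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        "<title>Profile HMM competition report</title></head><body>",
        "<table border='1'>",
        "<tr>" + "".join(f"<th>{_html.escape(c)}</th>" for c in cols)
        + "</tr>",
    ]
    for row in rows:
        parts.append(
            "<tr>"
            + "".join(f"<td>{_html.escape(_cell(row, c))}</td>" for c in cols)
            + "</tr>"
        )
    parts += ["</table>", "</body></html>"]
    return "\n".join(parts) + "\n"
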