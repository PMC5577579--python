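"""Profile hidden Markov models for peptide family classification.

A profile HMM summarises a multiple sequence alignment of a structurally
conserved peptide group as a chain of match states (one per conserved
alignment column) with insert and delete states allowing length variation.
Sequences are scored by the best *local* alignment of any contiguous
sequence segment against any sub-path of the model, reported as a bit
score: log2 of the ratio between the path probability and the probability
of the same segment under an i.i.d. background (null) model.

The classification workflow downstream uses only the single best-scoring
domain per model/sequence pair; no E-values are computed because the bit
score is independent of database size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical amino-acid ordering (alphabetical one-letter codes), the same
#: ordering used in HMMER3 ASCII profile files.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues accepted in sequences but scored neutrally (log-odds 0):
#: ambiguity codes and selenocysteine.
AMBIGUOUS_RESIDUES = "XBZU"

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Amino-acid frequencies from large curated protein collections (Swiss-Prot
# composition, rounded); selectable as an alternative null model.
SWISSPROT_FREQUENCIES = np.array([
    0.0826, 0.0137, 0.0546, 0.0672, 0.0386, 0.0708, 0.0227, 0.0593,
    0.0580, 0.0965, 0.0241, 0.0406, 0.0472, 0.0393, 0.0553, 0.0660,
    0.0535, 0.0687, 0.0110, 0.0292,
])
SWISSPROT_FREQUENCIES = SWISSPROT_FREQUENCIES / SWISSPROT_FREQUENCIES.sum()

# Transition column order, matching the HMMER3 profile text layout.
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)


@dataclass
class BuildParams:
    """Parameters controlling profile construction from an alignment.

    match_gap_fraction: columns whose gap fraction is strictly below this
        threshold become match states (default 0.5).
    pseudocount_weight: weight of the background-mixing pseudocount added
        to every emission and transition count (default 1.0).
    background_choice: ``"uniform"`` (1/20 for every residue) or
        ``"swissprot"`` (fixed composition table).
    """

    match_gap_fraction: float = 0.5
    pseudocount_weight: float = 1.0
    background_choice: str = "uniform"

    def background(self) -> np.ndarray:
        if self.background_choice == "uniform":
            return np.full(20, 0.05)
        if self.background_choice == "swissprot":
            return SWISSPROT_FREQUENCIES.copy()
        raise ValueError(
            f"unknown background_choice: {self.background_choice!r}"
        )


@dataclass
class ProfileHMM:
    """A protein profile HMM with per-node emission and transition tables.

    ``transitions[k]`` holds the seven per-node probabilities in the order
    M->M, M->I, M->D, I->M, I->I, D->M, D->D for node ``k`` (node 0 is the
    begin node; its M row describes begin transitions). Local alignment
    entry and exit are uniform over match states and carry no probability
    cost, so flanking sequence never penalises the best domain.
    """

    name: str
    desc: str
    length: int
    match_emissions: np.ndarray  # (M, 20)
    insert_emissions: np.ndarray  # (M+1, 20)
    transitions: np.ndarray  # (M+1, 7)
    background: np.ndarray  # (20,)

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.length < 1:
            raise ValueError("profile must have at least one match state")
        if self.match_emissions.shape != (self.length, 20):
            raise ValueError("match_emissions shape mismatch")
        if self.insert_emissions.shape != (self.length + 1, 20):
            raise ValueError("insert_emissions shape mismatch")
        if self.transitions.shape != (self.length + 1, 7):
            raise ValueError("transitions shape mismatch")

    def validate(self, atol: float = 1e-9) -> None:
        """Check that every stochastic parameter group sums to one."""
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=atol):
            raise ValueError(f"{self.name}: match emissions do not normalise")
        if not np.allclose(self.insert_emissions.sum(axis=1), 1.0, atol=atol):
            raise ValueError(f"{self.name}: insert emissions do not normalise")
        if abs(self.background.sum() - 1.0) > atol:
            raise ValueError(f"{self.name}: background does not normalise")
        t = self.transitions
        groups = (t[:, [T_MM, T_MI, T_MD]], t[:, [T_IM, T_II]],
                  t[:, [T_DM, T_DD]])
        for block in groups:
            if not np.allclose(block.sum(axis=1), 1.0, atol=atol):
                raise ValueError(f"{self.name}: transitions do not normalise")

    def consensus(self) -> str:
        """Most probable residue of each match state."""
        idx = np.argmax(self.match_emissions, axis=1)
        return "".join(AMINO_ACIDS[i] for i in idx)


@dataclass
class DomainHit:
    """Best local alignment of one model within one sequence.

    Coordinates are 1-based and inclusive, covering exactly the residues
    emitted by the alignment path.
    """

    model_name: str
    seq_id: str
    ali_from: int
    ali_to: int
    bit_score: float


def residue_indices(residues: str) -> np.ndarray:
    """Map residues to alphabet indices; ambiguity codes map to -1."""
    out = np.empty(len(residues), dtype=np.int64)
    for i, ch in enumerate(residues):
        if ch in _AA_INDEX:
            out[i] = _AA_INDEX[ch]
        elif ch in AMBIGUOUS_RESIDUES:
            out[i] = -1
        else:
            raise ValueError(f"invalid residue {ch!r} at position {i + 1}")
    return out


def _column_states(row: str, is_match: list[bool]) -> list[tuple[str, int]]:
    # State path of one alignment row: begin node 0, then M/D per match
    # column and I per occupied insert column.
    path = [("M", 0)]
    node = 0
    for ch, m in zip(row, is_match):
        if m:
            node += 1
            path.append(("M" if ch != "-" else "D", node))
        elif ch != "-":
            path.append(("I", node))
    path.append(("E", node + 1))
    return path


def build_profile(msa, params: BuildParams | None = None,
                  name: str = "model", desc: str = "") -> ProfileHMM:
    """Estimate a profile HMM from an alignment.

    Columns with gap fraction strictly below ``params.match_gap_fraction``
    become match states. Emissions and transitions are maximum-likelihood
    counts mixed with a single background pseudocount:
    ``P = (count + w * prior) / (total + w)``, with the background as the
    emission prior and a uniform prior over the legal options of each
    transition group.
    """
    params = params or BuildParams()
    rows = [aligned for _sid, aligned in msa.rows]
    if not rows:
        raise ValueError("empty alignment")
    n_rows = len(rows)
    width = len(rows[0])
    bg = params.background()
    w = params.pseudocount_weight

    gap_fraction = [
        sum(1 for r in rows if r[c] == "-") / n_rows for c in range(width)
    ]
    is_match = [f < params.match_gap_fraction for f in gap_fraction]
    m_count = sum(is_match)
    if m_count == 0:
        raise ValueError(
            "no alignment column qualifies as a match state; "
            "the alignment is too gappy to model"
        )

    match_counts = np.zeros((m_count, 20))
    insert_counts = np.zeros((m_count + 1, 20))
    trans_counts = np.zeros((m_count + 1, 7))

    for row in rows:
        node = 0
        for c, ch in enumerate(row):
            if is_match[c]:
                node += 1
                if ch != "-":
                    idx = _AA_INDEX.get(ch)
                    if idx is None:
                        if ch not in AMBIGUOUS_RESIDUES:
                            raise ValueError(
                                f"invalid residue {ch!r} in column {c + 1}"
                            )
                    else:
                        match_counts[node - 1, idx] += 1
            elif ch != "-":
                idx = _AA_INDEX.get(ch)
                if idx is None and ch not in AMBIGUOUS_RESIDUES:
                    raise ValueError(f"invalid residue {ch!r} in column {c + 1}")
                if idx is not None:
                    insert_counts[node, idx] += 1
        path = _column_states(row, is_match)
        for (s1, n1), (s2, _n2) in zip(path, path[1:]):
            src = n1
            if s1 == "M":
                col = {"M": T_MM, "I": T_MI, "D": T_MD, "E": T_MM}[s2]
            elif s1 == "I":
                col = {"M": T_IM, "I": T_II, "E": T_IM}[s2]
            else:  # D
                col = {"M": T_DM, "D": T_DD, "E": T_DM}[s2]
            trans_counts[src, col] += 1

    match_em = (match_counts + w * bg) / (
        match_counts.sum(axis=1, keepdims=True) + w
    )
    insert_em = (insert_counts + w * bg) / (
        insert_counts.sum(axis=1, keepdims=True) + w
    )

    trans = np.zeros((m_count + 1, 7))
    for k in range(m_count + 1):
        last = k == m_count
        m_opts = [T_MM, T_MI] if last else [T_MM, T_MI, T_MD]
        for opts in (m_opts, [T_IM, T_II], [T_DM, T_DD]):
            counts = trans_counts[k, opts]
            trans[k, opts] = (counts + w / len(opts)) / (counts.sum() + w)
        if last:
            trans[k, T_MD] = 0.0
            trans[k, [T_DM, T_DD]] = (1.0, 0.0)
    # Node 0 has no delete state; fix the conventional values.
    trans[0, [T_DM, T_DD]] = (1.0, 0.0)

    model = ProfileHMM(
        name=name, desc=desc, length=m_count,
        match_emissions=match_em, insert_emissions=insert_em,
        transitions=trans, background=bg,
    )
    model.validate(atol=1e-9)
    return model


_NEG_INF = float("-inf")


def _log_odds_tables(model: ProfileHMM):
    with np.errstate(divide="ignore"):
        lm = np.log2(model.match_emissions) - np.log2(model.background)
        li = np.log2(model.insert_emissions[1:]) - np.log2(model.background)
        lt = np.log2(model.transitions)
    return lm, li, lt


def _emission_scores(table: np.ndarray, idx: np.ndarray) -> np.ndarray:
    # (L, K) log-odds; ambiguity codes contribute 0 bits.
    out = np.zeros((len(idx), table.shape[0]))
    known = idx >= 0
    out[known] = table[:, idx[known]].T
    return out


def viterbi_best_domain(model: ProfileHMM, seq) -> DomainHit | None:
    """Best-scoring local alignment (single best domain) of ``model`` in
    ``seq``, or ``None`` when no segment scores above 0 bits.

    Alignment paths enter at any match state, traverse match/insert/delete
    states under the model transitions, and exit after any match state;
    entry and exit are free, so the score is a pure segment log-odds.
    """
    res = seq.residues
    if len(res) < 1:
        raise ValueError("sequence must contain at least one residue")
    idx = residue_indices(res)
    lm, li, lt = _log_odds_tables(model)
    L, M = len(res), model.length
    em = _emission_scores(lm, idx)  # (L, M)
    ei = _emission_scores(li, idx)  # (L, M) insert states 1..M (M unused)

    vm = np.full((L, M), _NEG_INF)
    vi = np.full((L, M), _NEG_INF)  # insert state k+1 at column k
    vd = np.full((L, M), _NEG_INF)  # delete state k+1 at column k
    sm = np.zeros((L, M), dtype=np.int64)  # start position trackers
    si = np.zeros((L, M), dtype=np.int64)
    sd = np.zeros((L, M), dtype=np.int64)

    tmm, tmi, tmd = lt[:, T_MM], lt[:, T_MI], lt[:, T_MD]
    tim, tii = lt[:, T_IM], lt[:, T_II]
    tdm, tdd = lt[:, T_DM], lt[:, T_DD]

    for i in range(L):
        # Match states: fresh entry (0 bits) or continuation from node k-1.
        best = np.zeros(M)
        start = np.full(M, i, dtype=np.int64)
        if i > 0:
            cand = np.full((3, M), _NEG_INF)
            cand_start = np.zeros((3, M), dtype=np.int64)
            cand[0, 1:] = vm[i - 1, :-1] + tmm[1:M]
            cand_start[0, 1:] = sm[i - 1, :-1]
            cand[1, 1:] = vi[i - 1, :-1] + tim[1:M]
            cand_start[1, 1:] = si[i - 1, :-1]
            cand[2, 1:] = vd[i - 1, :-1] + tdm[1:M]
            cand_start[2, 1:] = sd[i - 1, :-1]
            which = np.argmax(cand, axis=0)
            cbest = cand[which, np.arange(M)]
            better = cbest > best
            best[better] = cbest[better]
            start[better] = cand_start[which, np.arange(M)][better]
        vm[i] = em[i] + best
        sm[i] = start

        # Delete states at column k (node k+1), sweep ascending.
        for k in range(1, M):
            d_open = vm[i, k - 1] + tmd[k]
            d_ext = vd[i, k - 1] + tdd[k] if k >= 2 else _NEG_INF
            if d_open >= d_ext:
                vd[i, k] = d_open
                sd[i, k] = sm[i, k - 1]
            else:
                vd[i, k] = d_ext
                sd[i, k] = sd[i, k - 1]

        # Insert states (inserts after match k, k = 1..M-1).
        if i > 0:
            i_open = vm[i - 1, : M - 1] + tmi[1:M]
            i_ext = vi[i - 1, : M - 1] + tii[1:M]
            take_open = i_open >= i_ext
            vi[i, : M - 1] = ei[i, : M - 1] + np.where(take_open, i_open, i_ext)
            si[i, : M - 1] = np.where(
                take_open, sm[i - 1, : M - 1], si[i - 1, : M - 1]
            )

    flat = int(np.argmax(vm))
    best_score = float(vm.flat[flat])
    if not best_score > 0.0:
        return None
    end_i, end_k = divmod(flat, M)
    return DomainHit(
        model_name=model.name,
        seq_id=seq.seq_id,
        ali_from=int(sm[end_i, end_k]) + 1,
        ali_to=end_i + 1,
        bit_score=best_score,
    )


def forward_score(model: ProfileHMM, seq) -> float:
    """Log2 sum of the odds of every local alignment path (diagnostic).

    Always at least the Viterbi best-domain bit score, since the sum over
    paths dominates the maximum.
    """
    res = seq.residues
    if len(res) < 1:
        raise ValueError("sequence must contain at least one residue")
    idx = residue_indices(res)
    lm, li, lt = _log_odds_tables(model)
    L, M = len(res), model.length
    em = _emission_scores(lm, idx)
    ei = _emission_scores(li, idx)

    fm = np.full((L, M), _NEG_INF)
    fi = np.full((L, M), _NEG_INF)
    fd = np.full((L, M), _NEG_INF)

    tmm, tmi, tmd = lt[:, T_MM], lt[:, T_MI], lt[:, T_MD]
    tim, tii = lt[:, T_IM], lt[:, T_II]
    tdm, tdd = lt[:, T_DM], lt[:, T_DD]

    for i in range(L):
        acc = np.zeros(M)  # entry path: odds 2^0
        if i > 0:
            acc = np.logaddexp2(acc, np.concatenate(
                ([_NEG_INF], fm[i - 1, :-1] + tmm[1:M])))
            acc = np.logaddexp2(acc, np.concatenate(
                ([_NEG_INF], fi[i - 1, :-1] + tim[1:M])))
            acc = np.logaddexp2(acc, np.concatenate(
                ([_NEG_INF], fd[i - 1, :-1] + tdm[1:M])))
        fm[i] = em[i] + acc
        for k in range(1, M):
            d = fm[i, k - 1] + tmd[k]
            if k >= 2:
                d = np.logaddexp2(d, fd[i, k - 1] + tdd[k])
            fd[i, k] = d
        if i > 0:
            fi[i, : M - 1] = ei[i, : M - 1] + np.logaddexp2(
                fm[i - 1, : M - 1] + tmi[1:M], fi[i - 1, : M - 1] + tii[1:M]
            )

    finite = fm[np.isfinite(fm)]
    if finite.size == 0:
        return _NEG_INF
    # log2-sum-exp over all (position, node) exit points
    mx = finite.max()
    return float(mx + np.log2(np.sum(np.exp2(finite - mx))))
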