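"""Seeded generator of toxin-like sequence families.

Families are defined by a cysteine scaffold (a spacing range pattern, or
none for short linear cationic peptides), a residue-class bias for the
inter-cysteine loops, and a per-residue substitution rate. Members of a
family share a generated consensus; substitutions never touch scaffold
cysteines and never introduce new cysteines, so the cysteine framework is
an invariant of the family. The default benchmark emulates held-out
family classification: distinct scaffolds drawn from published spacing
patterns (huwentoxin-1 group spacings and the ICK ranges) plus one linear
cationic family, with a 2/3-train / 1/3-test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .competition import CompeteOptions, compete
from .grouping import ICK_PATTERN, RangePattern, group_sequences
from .io_formats import Msa, SequenceRecord
from .profile_hmm import BuildParams, ProfileHMM, build_profile

# Loop residue palettes; cysteine is deliberately absent from every
# palette so that loop sampling cannot alter a scaffold's framework.
_PALETTES = {
    "charged": "DEKRH",
    "polar-uncharged": "STNQY",
    "hydrophobic": "AVLIMFW",
    "small": "GP",
    "cationic": "KRKRAGLIS",  # lysine/arginine-rich amphipathic flavour
}
_NON_CYS = "ADEFGHIKLMNPQRSTVWY"


@dataclass
class FamilySpec:
    """Recipe for one synthetic family.

    ``scaffold`` is a spacing range pattern (``None`` for linear
    peptides, in which case ``linear_length`` applies). ``loop_class``
    biases non-cysteine residues toward one property class (``None`` for
    a uniform non-cysteine composition); a list gives one class per
    region (leading flank, gaps..., trailing flank).
    """

    name: str
    scaffold: RangePattern | None
    loop_class: str | list[str | None] | None = None
    members: int = 30
    mutation_rate: float = 0.1
    seed: int = 0
    linear_length: int = 25

    def __post_init__(self) -> None:
        if self.members < 2:
            raise ValueError("a family needs at least 2 members")
        if not 0.0 <= self.mutation_rate <= 0.5:
            raise ValueError("mutation_rate must lie in [0, 0.5]")


def _region_ranges(spec: FamilySpec) -> list[tuple[int, int]]:
    if spec.scaffold is None:
        return [(spec.linear_length, spec.linear_length)]
    lead = spec.scaffold.leading or (0, 0)
    trail = spec.scaffold.trailing or (0, 0)
    return [lead, *spec.scaffold.gap_ranges, trail]


def _region_palette(spec: FamilySpec, region_idx: int) -> str:
    lc = spec.loop_class
    if isinstance(lc, list):
        lc = lc[region_idx % len(lc)]
    if lc is None:
        return _NON_CYS
    return _PALETTES[lc]


def _generate_regions(spec: FamilySpec):
    """Per-member region strings plus the per-region maximum widths."""
    rng = np.random.default_rng(spec.seed)
    ranges = _region_ranges(spec)
    consensus = [
        "".join(rng.choice(list(_region_palette(spec, i)), size=hi))
        for i, (_lo, hi) in enumerate(ranges)
    ]
    members = []
    for _m in range(spec.members):
        regions = []
        for i, (lo, hi) in enumerate(ranges):
            length = int(rng.integers(lo, hi + 1)) if hi > lo else hi
            regions.append(consensus[i][:length])
        # point substitutions on loop residues only (never a cysteine,
        # never introducing one)
        mutated = []
        for region in regions:
            chars = list(region)
            for j, ch in enumerate(chars):
                if spec.mutation_rate > 0 and rng.random() < spec.mutation_rate:
                    choices = [c for c in _NON_CYS if c != ch]
                    chars[j] = str(rng.choice(choices))
            mutated.append("".join(chars))
        members.append(mutated)
    return members, [hi for (_lo, hi) in ranges]


def _assemble(regions: list[str], with_cysteines: bool) -> str:
    if not with_cysteines:
        return regions[0]
    parts = [regions[0]]
    for region in regions[1:]:
        parts.append("C")
        parts.append(region)
    # regions = [leading, gap1.., trailing]: cysteines separate them
    return "".join(parts)


def generate_family(spec: FamilySpec
                    ) -> tuple[list[SequenceRecord],
                               list[tuple[str, str]]]:
    """Generate the members of one family with their true labels.

    Fully deterministic given ``spec.seed``; the scaffold cysteines are
    identical across members, so every member shares the family
    framework.
    """
    member_regions, _widths = _generate_regions(spec)
    records = []
    labels = []
    for m, regions in enumerate(member_regions):
        seq_id = f"{spec.name}|{m:03d}"
        residues = _assemble(regions, spec.scaffold is not None)
        records.append(SequenceRecord(
            seq_id=seq_id, description=f"synthetic member of {spec.name}",
            residues=residues,
        ))
        labels.append((seq_id, spec.name))
    return records, labels


def generate_family_msa(spec: FamilySpec) -> tuple[list[SequenceRecord], Msa]:
    """Members plus their ground-truth alignment (regions padded with
    gaps to each region's maximum width)."""
    member_regions, widths = _generate_regions(spec)
    records, _labels = generate_family(spec)
    rows = []
    for rec, regions in zip(records, member_regions):
        padded = [r + "-" * (w - len(r)) for r, w in zip(regions, widths)]
        rows.append((rec.seq_id, _assemble(padded, spec.scaffold is not None)))
    return records, Msa(name=spec.name, rows=rows)


def _fixed(gaps: list[int], leading: int = 3, trailing: int = 3
           ) -> RangePattern:
    return RangePattern(
        gap_ranges=tuple((g, g) for g in gaps),
        leading=(leading, leading), trailing=(trailing, trailing),
    )


def default_family_specs(seed: int = 1) -> list[FamilySpec]:
    """Ten pairwise-distinct family recipes.

    Three use the published huwentoxin-1 group spacings ([6,5,0,4,8],
    [6,6,0,4,6], [6,5,0,4,7] on the C-C-CC-C-C framework), six use fixed
    spacings sampled inside the ICK ranges, and one is a linear cationic
    family. Loop-class biases cycle across families.
    """
    rng = np.random.default_rng(seed)
    classes = ["polar-uncharged", "hydrophobic", "charged", "small"]
    specs: list[FamilySpec] = []
    fixed_gaps = [
        [6, 5, 0, 4, 8],  # huwentoxin-1 group SN_10_01 spacing
        [6, 6, 0, 4, 6],  # SN_10_04 spacing
        [6, 5, 0, 4, 7],  # SN_10_05 spacing
    ]
    used = {tuple(g) for g in fixed_gaps}
    for i, gaps in enumerate(fixed_gaps):
        specs.append(FamilySpec(
            name=f"fam{i + 1:02d}",
            scaffold=_fixed(gaps),
            loop_class=classes[i % len(classes)],
            members=30, mutation_rate=0.1,
            seed=seed * 1000 + i,
        ))
    # six fixed scaffolds sampled inside the ICK spacing ranges
    i = len(fixed_gaps)
    while i < 9:
        gaps = tuple(
            int(rng.integers(lo, hi + 1)) for lo, hi in ICK_PATTERN.gap_ranges
        )
        if gaps in used:
            continue
        used.add(gaps)
        t_lo, t_hi = ICK_PATTERN.trailing
        trailing = int(rng.integers(t_lo, t_hi + 1))
        specs.append(FamilySpec(
            name=f"fam{i + 1:02d}",
            scaffold=_fixed(list(gaps), leading=6, trailing=trailing),
            loop_class=classes[i % len(classes)],
            members=30, mutation_rate=0.1,
            seed=seed * 1000 + i,
        ))
        i += 1
    specs.append(FamilySpec(
        name="fam10",
        scaffold=None, loop_class="cationic",
        members=30, mutation_rate=0.1, linear_length=25,
        seed=seed * 1000 + 9,
    ))
    return specs


@dataclass
class Benchmark:
    train: list[SequenceRecord]
    test: list[SequenceRecord]
    labels: dict[str, str]
    specs: list[FamilySpec]


def benchmark_default(seed: int = 1, train_fraction: float = 2 / 3
                      ) -> Benchmark:
    """The packaged benchmark: 10 families x 30 members, 20 train / 10
    test per family (200 train, 100 test at the defaults)."""
    specs = default_family_specs(seed)
    train: list[SequenceRecord] = []
    test: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    for spec in specs:
        records, fam_labels = generate_family(spec)
        labels.update(dict(fam_labels))
        n_train = round(spec.members * train_fraction)
        train.extend(records[:n_train])
        test.extend(records[n_train:])
    return Benchmark(train=train, test=test, labels=labels, specs=specs)


@dataclass
class BenchmarkResult:
    sensitivity: float
    n_test: int
    n_correct: int
    n_groups: int
    models: list[ProfileHMM]
    model_to_family: dict[str, str]


def run_benchmark(seed: int = 1,
                  params: BuildParams | None = None) -> BenchmarkResult:
    """End-to-end held-out evaluation: group the training sequences,
    build one profile per structural group, compete on the test set, and
    measure the fraction of test sequences won by a model of their true
    family (unmatched sequences count as errors)."""
    bench = benchmark_default(seed)
    groups = group_sequences(bench.train)
    by_id = {rec.seq_id: rec for rec in bench.train}

    models: list[ProfileHMM] = []
    model_to_family: dict[str, str] = {}
    for g_idx, group in enumerate(groups):
        members = [by_id[sid] for sid in group.members]
        fams = [bench.labels[sid] for sid in group.members]
        family = max(set(fams), key=fams.count)
        rows = [(rec.seq_id, rec.residues) for rec in members]
        msa = Msa(name=f"group{g_idx:02d}", rows=rows)
        name = f"G{g_idx:02d}"
        model = build_profile(msa, params, name=name, desc=family)
        models.append(model)
        model_to_family[name] = family

    rows = compete(models, bench.test, CompeteOptions(show_allseq=True))
    n_correct = sum(
        1 for row in rows
        if row.matched
        and model_to_family[row.classifier_name] == bench.labels[row.sequence_id]
    )
    n_test = len(bench.test)
    return BenchmarkResult(
        sensitivity=n_correct / n_test,
        n_test=n_test,
        n_correct=n_correct,
        n_groups=len(groups),
        models=models,
        model_to_family=model_to_family,
    )
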