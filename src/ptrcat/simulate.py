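"""Seeded generator of reference/target sequence pairs with a planted,
known tandem-repeat polymorphism — the test substrate for the whole pipeline.

The model: a genic reference sequence carries one TR (motif repeated
``units_ref`` times, each unit optionally carrying one substitution — the
"fuzziness" of the repeat itself). The target genome holds the same locus
with ``delta_units`` motif copies added at the repeat's end (or removed from
it) and with flanks diverged by independent per-base substitutions and
single-base indels. The repeat sequence is mutated once and shared by
reference and target: the two assemblies descend from one haplotype, and
flank SNPs/indels plus an optional target-only unit divergence model what
separates them. Optional extras plant a >= 10 bp N stretch (to exercise the
N filter) and a duplicate copy of the left flank (to exercise ambiguous
placement).

Not modelled: realistic genome background (GC structure, genome-scale
segmental duplications), multi-base indels, heterozygosity.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np

from .model import GenomicInterval, TRCandidate

__all__ = ["FixtureSpec", "FixtureTruth", "make_fixture", "make_cohort",
           "default_spec_sampler"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixtureSpec:
    motif: Union[str, int] = 3          # motif string, or length to draw
    units_ref: int = 20
    delta_units: int = 0
    flank_bp: int = 400
    flank_snp_rate: float = 0.01        # per base, target flanks only
    flank_indel_rate: float = 0.0       # per base, single-base indels
    tr_unit_mutation_rate: float = 0.03  # per unit, shared ref/target
    target_unit_mutation_rate: float = 0.0  # per unit, target only
    n_stretch: Optional[tuple[int, int]] = None  # (offset in TR, length)
    duplicate_left_flank: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.units_ref < 2:
            raise ValueError("units_ref must be >= 2")
        if self.units_ref + self.delta_units < 0:
            raise ValueError("target unit count would be negative")
        for rate in (self.flank_snp_rate, self.flank_indel_rate,
                     self.tr_unit_mutation_rate,
                     self.target_unit_mutation_rate):
            if not (0.0 <= rate <= 0.2):
                raise ValueError("rates must be within [0, 0.2]")


@dataclass(frozen=True)
class FixtureTruth:
    reference_sequence: str
    target_sequence: str
    tr_interval_ref: GenomicInterval
    tr_interval_target: Optional[GenomicInterval]
    planted_delta: int
    motif: str
    units_ref: int
    spec: FixtureSpec = field(repr=False)

    def reference_candidate(self, tool: str = "planted") -> TRCandidate:
        """The planted TR as a candidate record (ground-truth detector)."""
        iv = self.tr_interval_ref
        return TRCandidate(
            interval=iv, motif=self.motif,
            unit_count_ref=float(self.units_ref),
            sequence=self.reference_sequence[iv.start:iv.end],
            source_tools=frozenset({tool}))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _random_motif(rng: np.random.Generator, length: int) -> str:
    # require >= 2 distinct bases so the motif is not a homopolymer
    while True:
        m = _random_seq(rng, length)
        if len(set(m)) >= 2 or length == 1:
            return m


def _mutate_unit(rng: np.random.Generator, unit: str) -> str:
    pos = int(rng.integers(len(unit)))
    old = unit[pos]
    new = old
    while new == old:
        new = chr(int(rng.choice(_BASES)))
    return unit[:pos] + new + unit[pos + 1:]


def _mutate_flank(rng: np.random.Generator, seq: str, snp_rate: float,
                  indel_rate: float) -> str:
    out = []
    for base in seq:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        if r < indel_rate:
            out.append(chr(int(rng.choice(_BASES))))  # insertion before base
        if rng.random() < snp_rate:
            new = base
            while new == base:
                new = chr(int(rng.choice(_BASES)))
            out.append(new)
        else:
            out.append(base)
    return "".join(out)


def make_fixture(spec: FixtureSpec) -> FixtureTruth:
    """Deterministically build one reference/target pair from a spec."""
    rng = np.random.default_rng(spec.seed)
    motif = (spec.motif if isinstance(spec.motif, str)
             else _random_motif(rng, spec.motif))
    if not (1 <= len(motif) <= 100):
        raise ValueError("motif length must be in [1, 100]")

    ref_units = []
    for _ in range(spec.units_ref):
        unit = motif
        if rng.random() < spec.tr_unit_mutation_rate:
            unit = _mutate_unit(rng, unit)
        ref_units.append(unit)

    units_target = spec.units_ref + spec.delta_units
    if spec.delta_units >= 0:
        tgt_units = ref_units + [motif] * spec.delta_units
    else:
        tgt_units = ref_units[:units_target]
    tgt_units = [
        _mutate_unit(rng, u)
        if rng.random() < spec.target_unit_mutation_rate else u
        for u in tgt_units
    ]

    tr_ref = "".join(ref_units)
    if spec.n_stretch is not None:
        off, length = spec.n_stretch
        if off < 0 or off + length > len(tr_ref):
            raise ValueError("n_stretch outside the reference TR")
        tr_ref = tr_ref[:off] + "N" * length + tr_ref[off + length:]
    tr_tgt = "".join(tgt_units)

    left = _random_seq(rng, spec.flank_bp)
    right = _random_seq(rng, spec.flank_bp)
    reference = left + tr_ref + right

    left_t = _mutate_flank(rng, left, spec.flank_snp_rate,
                           spec.flank_indel_rate)
    right_t = _mutate_flank(rng, right, spec.flank_snp_rate,
                            spec.flank_indel_rate)
    prefix = ""
    if spec.duplicate_left_flank:
        prefix = left + _random_seq(rng, 50)
    target = prefix + left_t + tr_tgt + right_t

    tr_start_t = len(prefix) + len(left_t)
    tr_iv_target = (GenomicInterval("target", tr_start_t,
                                    tr_start_t + len(tr_tgt))
                    if tr_tgt else None)
    return FixtureTruth(
        reference_sequence=reference,
        target_sequence=target,
        tr_interval_ref=GenomicInterval("ref", len(left),
                                        len(left) + len(tr_ref)),
        tr_interval_target=tr_iv_target,
        planted_delta=spec.delta_units,
        motif=motif,
        units_ref=spec.units_ref,
        spec=spec,
    )


def default_spec_sampler(
    delta_choices: tuple[int, ...] = (-5, -4, -3, -2, -1, 1, 2, 3, 4, 5),
    units_range: tuple[int, int] = (8, 30),
    motif_lengths: tuple[int, ...] = (2, 3, 4, 5, 6),
    flank_snp_rate: float = 0.01,
    flank_indel_rate: float = 0.0,
    tr_unit_mutation_rate: float = 0.03,
    flank_bp: int = 400,
) -> Callable[[np.random.Generator, int], FixtureSpec]:
    """Factory for a cohort sampler over the standard study conditions."""

    def sample(rng: np.random.Generator, seed: int) -> FixtureSpec:
        return FixtureSpec(
            motif=int(rng.choice(motif_lengths)),
            units_ref=int(rng.integers(units_range[0], units_range[1] + 1)),
            delta_units=int(rng.choice(delta_choices)),
            flank_bp=flank_bp,
            flank_snp_rate=flank_snp_rate,
            flank_indel_rate=flank_indel_rate,
            tr_unit_mutation_rate=tr_unit_mutation_rate,
            seed=seed,
        )

    return sample


def make_cohort(
    n: int,
    spec_distribution: Optional[Callable[[np.random.Generator, int],
                                         FixtureSpec]] = None,
    seed: int = 0,
) -> list[FixtureTruth]:
    """n independent fixtures with spec parameters drawn from
    ``spec_distribution`` (default: :func:`default_spec_sampler` conditions);
    reproducible under ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = spec_distribution or default_spec_sampler()
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    return [make_fixture(sampler(rng, int(s))) for s in child_seeds]
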