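"""Seeded synthetic-data generators.

Everything the other modules consume can be generated here without any
download: toy transcriptomes (optionally with a readthrough transcript
embedding a targeted gene segment, emulating the off-target capture of a
gene-fusion readthrough), a 10-member ssDNA mixture in the 20–190-nt
range, cDNA-like fragment libraries with a 150–700-nt size distribution,
and matched control/treated coverage pairs produced by probabilistically
removing fragments that overlap probe binding sites.

All generators are pure functions of (config, seed): repeated calls are
byte-identical.  Base composition is uniform — the design and evaluation
logic is composition-agnostic, so no GC or codon realism is attempted.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .csl_design import CatcherLibrary
from .depletion_eval import CoverageTrack
from .pulldown_sim import MixtureMember
from .seqcore import Interval, Sequence, longest_shared_substring

__all__ = [
    "FixtureConfig",
    "Fragment",
    "make_adapter",
    "make_transcriptome",
    "make_ssdna_library",
    "make_fragment_library",
    "simulate_depleted_coverage",
]

_ALPHABET = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the synthetic generators.

    Defaults: 20 genes of 400–2500 nt; a "dominated" abundance model in
    which the first ``n_dominant`` (3) genes jointly hold
    ``dominant_fraction`` (50%) of the molecule mass, emulating a library
    in which a few high-abundance transcripts consume a large share of
    reads; fragment lengths uniform in 150–700 nt; 1e5 fragments per
    fixture.
    """

    seed: int = 0
    n_genes: int = 20
    length_range: tuple[int, int] = (400, 2500)
    abundance: str = "dominated"  # or "uniform"
    n_dominant: int = 3
    dominant_fraction: float = 0.5
    fragment_range: tuple[int, int] = (150, 700)
    reads: int = 100_000

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        flo, fhi = self.fragment_range
        if not (0 < lo <= hi and 0 < flo <= fhi):
            raise ValueError("length bounds must be positive and ordered")
        if not 0.0 <= self.dominant_fraction <= 1.0:
            raise ValueError("dominant_fraction must be in [0, 1]")
        if self.abundance not in ("uniform", "dominated"):
            raise ValueError(f"unknown abundance model {self.abundance!r}")


@dataclass(frozen=True)
class Fragment:
    """One sequenced fragment with its origin interval."""

    transcript_id: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Interval:
        return Interval(self.transcript_id, self.start, self.end)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=n))


def make_adapter(seed: int = 0, length: int = 22) -> Sequence:
    """A random adapter/anchor-complement sequence of the standard 22 nt."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xADA])
    return Sequence("adapter", _random_bases(rng, length))


def make_transcriptome(
    config: FixtureConfig,
    readthrough: bool = False,
    shared_len: int = 38,
) -> list[Sequence]:
    """Random transcripts G01..Gnn, uniform base composition.

    With ``readthrough`` an extra transcript ``G01_RT`` is appended that
    embeds a ``shared_len``-nt segment copied from the middle of G01 —
    the constructed analogue of a readthrough gene sharing a targeted
    gene's sequence, which an off-target screen must flag.
    """
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 1])
    lo, hi = config.length_range
    transcripts = []
    for i in range(config.n_genes):
        n = int(rng.integers(lo, hi + 1))
        transcripts.append(Sequence(f"G{i + 1:02d}", _random_bases(rng, n)))
    if readthrough:
        if not transcripts:
            raise ValueError("readthrough requires at least one gene")
        donor = transcripts[0]
        if len(donor) < shared_len:
            raise ValueError("donor transcript shorter than the shared segment")
        # align to the default tiling grid so a full-length design of the
        # donor has one binding site entirely inside the shared segment
        mid = ((len(donor) - shared_len) // 2 // shared_len) * shared_len
        segment = donor.bases[mid : mid + shared_len]
        flank_left = _random_bases(rng, 200)
        flank_right = _random_bases(rng, 200)
        transcripts.append(Sequence(f"{donor.id}_RT", flank_left + segment + flank_right))
    return transcripts


def make_ssdna_library(
    config: FixtureConfig,
    n_members: int = 10,
    molecules: int = 100_000,
    max_shared: int = 15,
) -> list[MixtureMember]:
    """A 10-member ssDNA mixture, members A–J, lengths in [20, 190] nt.

    Members are rejection-sampled until no pair shares more than
    ``max_shared`` contiguous bases on either strand, so that target
    classification by >= 16-nt complementarity cannot cross-react.
    """
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 2])
    names = list(string.ascii_uppercase[:n_members])
    members: list[MixtureMember] = []
    for name in names:
        while True:
            n = int(rng.integers(20, 191))
            bases = _random_bases(rng, n)
            if all(
                longest_shared_substring(bases, m.sequence, both_strands=True).length
                <= max_shared
                for m in members
            ):
                break
        members.append(MixtureMember(name, Sequence(name, bases), molecules))
    return members


def make_fragment_library(
    transcriptome: Iterable[Sequence], config: FixtureConfig
) -> list[Fragment]:
    """cDNA-like fragments sampled from the transcriptome.

    Each fragment picks its transcript according to the abundance model
    (uniform, or "dominated": the first ``n_dominant`` genes share
    ``dominant_fraction`` of the mass equally), a length uniform in
    ``fragment_range`` clipped to the transcript length, and a uniform
    start — so short transcripts yield whole-length fragments and long
    ones a uniform pileup away from the ends.
    """
    transcripts = list(transcriptome)
    if not transcripts:
        return []
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 3])
    k = len(transcripts)
    if config.abundance == "dominated" and k > config.n_dominant:
        nd = config.n_dominant
        weights = np.empty(k)
        weights[:nd] = config.dominant_fraction / nd
        weights[nd:] = (1.0 - config.dominant_fraction) / (k - nd)
    else:
        weights = np.full(k, 1.0 / k)
    flo, fhi = config.fragment_range
    idx = rng.choice(k, size=config.reads, p=weights)
    lengths = rng.integers(flo, fhi + 1, size=config.reads)
    fragments = []
    for i, raw_len in zip(idx, lengths):
        t = transcripts[i]
        frag_len = min(int(raw_len), len(t))
        start = int(rng.integers(0, len(t) - frag_len + 1))
        fragments.append(Fragment(t.id, start, start + frag_len))
    return fragments


def _pileup(fragments: Iterable[Fragment], lengths: Mapping[str, int]) -> dict[str, CoverageTrack]:
    delta = {tid: np.zeros(n + 1, dtype=np.int64) for tid, n in lengths.items()}
    for f in fragments:
        d = delta[f.transcript_id]
        d[f.start] += 1
        d[f.end] -= 1
    return {
        tid: CoverageTrack(tid, np.cumsum(d[:-1])) for tid, d in delta.items()
    }


def simulate_depleted_coverage(
    fragments: Iterable[Fragment],
    transcriptome: Iterable[Sequence],
    csl: CatcherLibrary,
    e: float = 0.9,
    min_match: int = 20,
    seed: int = 0,
) -> tuple[dict[str, CoverageTrack], dict[str, CoverageTrack], np.ndarray]:
    """Control/treated coverage pair from probabilistic fragment removal.

    Control coverage piles up every fragment; treated coverage removes,
    with probability ``e``, each fragment overlapping any CSL binding-site
    interval by at least ``min_match`` bases.  Returns (control, treated,
    removal manifest); removed + retained = total.  Because fragments
    extend up to the maximum fragment length past a targeted region, the
    resulting per-base depletion decays with distance from the region and
    vanishes beyond one fragment length.
    """
    if not 0.0 <= e <= 1.0:
        raise ValueError("capture probability e must be in [0, 1]")
    fragments = list(fragments)
    lengths = {t.id: len(t) for t in transcriptome}
    targeted = csl.targeted_intervals
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 4])
    removed = np.zeros(len(fragments), dtype=bool)
    for i, f in enumerate(fragments):
        ivs = targeted.get(f.transcript_id, ())
        hit = any(
            min(f.end, iv.end) - max(f.start, iv.start) >= min_match for iv in ivs
        )
        if hit and rng.random() < e:
            removed[i] = True
    control = _pileup(fragments, lengths)
    treated = _pileup(
        (f for f, rm in zip(fragments, removed) if not rm), lengths
    )
    return control, treated, removed
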