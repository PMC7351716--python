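"""Catcher-strand library (CSL) design.

A catcher strand is a three-domain oligonucleotide probe, written 5'→3' as

    [release site] [binding site] [adapter]

The binding site hybridizes the DNA target; the adapter hybridizes the
anchor strand grafted to the pulldown polymer; the optional release site
is a single-stranded toehold where a release strand nucleates to evict
the bound target by strand displacement.  A library tiles one or more
target regions with contiguous binding sites, alternating between probes
that bind the sense strand and probes that bind the antisense strand, so
that both strands of a denatured duplex target are captured and their
re-hybridization is blocked.
"""

from __future__ import annotations

import io
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence as _Seq

import numpy as np

from .seqcore import (
    Interval,
    Sequence,
    longest_shared_substring,
    reverse_complement,
    write_fasta,
)

__all__ = [
    "SENSE",
    "ANTISENSE",
    "DesignError",
    "UniquenessError",
    "DenaturationOnlyError",
    "DesignParams",
    "CatcherStrand",
    "CatcherLibrary",
    "ReleaseStrand",
    "OfftargetHit",
    "tile_region",
    "build_catcher",
    "design_release_strand",
    "design_csl",
    "screen_offtargets",
    "order_sheet",
    "release_sheet",
    "read_order_sheet",
    "write_library",
]

SENSE = "sense"
ANTISENSE = "antisense"
_STRANDS = (SENSE, ANTISENSE)


class DesignError(ValueError):
    """A design precondition is violated (region too short, missing adapter...)."""


class UniquenessError(DesignError):
    """Two catchers in one library share a binding-site sequence."""

    def __init__(self, collisions: list[tuple[str, str]]):
        self.collisions = collisions
        pairs = "; ".join(f"{a} == {b}" for a, b in collisions)
        super().__init__(f"duplicate binding sites in library: {pairs}")


class DenaturationOnlyError(DesignError):
    """The catcher has no release site: targets can only be recovered by
    thermal or basic denaturation, not by strand displacement."""


@dataclass(frozen=True)
class DesignParams:
    """Library-wide design parameters.

    ``binding_len`` (38 nt) and the 22-nt adapter match the published
    probe architecture; ``release_len`` 10 nt is a typical strand
    displacement toehold (6–10 nt).  ``step`` is the tile start
    increment: ``None`` means contiguous tiles of exactly
    ``binding_len``; a larger value leaves gaps, a smaller one overlaps.
    ``seed`` drives release-site generation only.
    """

    adapter_seq: "Sequence | str | None" = None
    binding_len: int = 38
    release_len: int = 10
    alternate: bool = True
    start_strand: str = SENSE
    min_offtarget_k: int = 16
    step: "int | None" = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.binding_len < 10:
            raise DesignError("binding_len must be >= 10 nt")
        if self.release_len < 0:
            raise DesignError("release_len must be >= 0")
        if self.start_strand not in _STRANDS:
            raise DesignError(f"start_strand must be one of {_STRANDS}")
        if isinstance(self.adapter_seq, str):
            object.__setattr__(self, "adapter_seq", Sequence("adapter", self.adapter_seq))

    @property
    def tile_step(self) -> int:
        return self.binding_len if self.step is None else self.step


@dataclass(frozen=True)
class CatcherStrand:
    """One designed probe tied to its target locus."""

    name: str
    target_interval: Interval
    bound_strand: str
    binding_site: Sequence
    adapter: Sequence
    release_site: "Sequence | None" = None

    @property
    def full_sequence(self) -> Sequence:
        """5'-[release][binding][adapter]-3' domain concatenation."""
        rel = self.release_site.bases if self.release_site else ""
        return Sequence(self.name, rel + self.binding_site.bases + self.adapter.bases)


@dataclass(frozen=True)
class ReleaseStrand:
    """TMSD release strand for one catcher: the exact reverse complement
    of the catcher's release + binding domains.  It nucleates at the
    single-stranded toehold and branch-migrates through the binding site,
    evicting the bound target; the released target carries no probe
    sequence."""

    catcher_name: str
    sequence: Sequence


@dataclass(frozen=True)
class OfftargetHit:
    catcher_name: str
    transcript_id: str
    shared_len: int
    catcher_interval: Interval
    transcript_interval: Interval
    strand: str


@dataclass
class CatcherLibrary:
    """A validated, deterministically ordered collection of catchers."""

    catchers: list[CatcherStrand]
    params: DesignParams
    targets: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.catchers)

    def __iter__(self):
        return iter(self.catchers)

    def validate(self) -> None:
        seen: dict[str, str] = {}
        collisions: list[tuple[str, str]] = []
        for c in self.catchers:
            if c.binding_site.bases in seen:
                collisions.append((seen[c.binding_site.bases], c.name))
            else:
                seen[c.binding_site.bases] = c.name
            if self.params.adapter_seq is not None and c.adapter.bases != self.params.adapter_seq.bases:
                raise DesignError(f"catcher {c.name} does not share the library adapter")
        if collisions:
            raise UniquenessError(collisions)
        if self.params.tile_step >= self.params.binding_len:
            by_tid: dict[str, list[Interval]] = {}
            for c in self.catchers:
                by_tid.setdefault(c.target_interval.transcript_id, []).append(c.target_interval)
            for ivs in by_tid.values():
                ivs = sorted(ivs, key=lambda iv: iv.start)
                for prev, nxt in zip(ivs, ivs[1:]):
                    if nxt.start < prev.end:
                        raise DesignError(
                            f"overlapping catcher intervals on {prev.transcript_id}"
                        )

    @property
    def targeted_intervals(self) -> dict[str, list[Interval]]:
        """Binding-site intervals per transcript, sorted by coordinate."""
        out: dict[str, list[Interval]] = {}
        for c in self.catchers:
            out.setdefault(c.target_interval.transcript_id, []).append(c.target_interval)
        return {tid: sorted(ivs, key=lambda iv: iv.start) for tid, ivs in out.items()}


# ---------------------------------------------------------------------------
# tiling and assembly


def tile_region(
    target: Sequence, region: Interval, params: DesignParams
) -> list[tuple[Interval, str]]:
    """Tile ``region`` with contiguous ``binding_len`` windows.

    Tiles start at ``region.start`` and advance by ``params.tile_step``;
    a trailing remainder shorter than ``binding_len`` is dropped, so with
    the default step the tile count is ``floor(len(region)/binding_len)``.
    The bound strand alternates tile-to-tile starting with
    ``start_strand`` when ``alternate`` is on, and is constant otherwise.
    """
    if region.transcript_id != target.id:
        raise DesignError(f"region {region.transcript_id} does not name target {target.id}")
    if region.end > len(target):
        raise DesignError(f"region {region.start}-{region.end} exceeds target {target.id}")
    if len(region) < params.binding_len:
        raise DesignError(
            f"region {region.transcript_id}:{region.start}-{region.end} is shorter "
            f"than binding_len={params.binding_len}"
        )
    tiles: list[tuple[Interval, str]] = []
    other = ANTISENSE if params.start_strand == SENSE else SENSE
    pos, i = region.start, 0
    while pos + params.binding_len <= region.end:
        strand = params.start_strand
        if params.alternate and i % 2 == 1:
            strand = other
        tiles.append((Interval(target.id, pos, pos + params.binding_len), strand))
        pos += params.tile_step
        i += 1
    return tiles


def _release_rng(params: DesignParams, key: str) -> np.random.Generator:
    return np.random.default_rng([params.seed & 0x7FFFFFFF, zlib.crc32(key.encode())])


def _generate_release_site(
    length: int,
    rng: np.random.Generator,
    screen_against: _Seq[Sequence],
    start_max_shared: int = 3,
    tries_per_level: int = 200,
) -> str:
    """Random toehold with minimal complementarity to any target.

    Rejection-samples candidates whose longest shared substring with every
    screened sequence (either strand) is at most ``start_max_shared``;
    the threshold relaxes by one after ``tries_per_level`` failures, so
    the procedure is deterministic and always terminates while keeping
    the toehold as single-stranded as the targets allow.
    """
    alphabet = np.array(list("ACGT"))
    thresh = min(start_max_shared, length)
    while True:
        for _ in range(tries_per_level):
            cand = "".join(rng.choice(alphabet, size=length))
            if all(
                longest_shared_substring(cand, t, both_strands=True).length <= thresh
                for t in screen_against
            ):
                return cand
        thresh += 1


def build_catcher(
    target: Sequence,
    tile: tuple[Interval, str],
    params: DesignParams,
    screen_against: "_Seq[Sequence] | None" = None,
) -> CatcherStrand:
    """Assemble the three-domain catcher for one tile.

    A sense-bound catcher carries the reverse complement of the sense
    segment; an antisense-bound catcher carries the sense segment
    verbatim (the complement of the antisense strand).  The release site,
    when ``release_len > 0``, is drawn from a seeded generator screened
    against ``screen_against`` (default: the target itself).
    """
    if params.adapter_seq is None:
        raise DesignError("adapter_seq must be set to build catcher strands")
    interval, strand = tile
    if strand not in _STRANDS:
        raise DesignError(f"unknown strand {strand!r}")
    segment = target.bases[interval.start : interval.end]
    binding = reverse_complement(segment) if strand == SENSE else segment
    name = f"{interval.transcript_id}_{interval.start}_{interval.end}_{strand[0]}"
    release = None
    if params.release_len > 0:
        rng = _release_rng(params, name)
        screened = list(screen_against) if screen_against is not None else [target]
        release = Sequence(
            f"{name}_toehold",
            _generate_release_site(params.release_len, rng, screened),
        )
    return CatcherStrand(
        name=name,
        target_interval=interval,
        bound_strand=strand,
        binding_site=Sequence(f"{name}_binding", binding),
        adapter=params.adapter_seq,
        release_site=release,
    )


def design_release_strand(catcher: CatcherStrand) -> ReleaseStrand:
    """Release strand = reverse complement of release + binding domains."""
    if catcher.release_site is None:
        raise DenaturationOnlyError(
            f"catcher {catcher.name} has no release site; its targets can only be "
            "recovered non-selectively by thermal or basic denaturation"
        )
    duplex_part = catcher.release_site.bases + catcher.binding_site.bases
    return ReleaseStrand(
        catcher_name=catcher.name,
        sequence=Sequence(f"{catcher.name}_rel", reverse_complement(duplex_part)),
    )


def design_csl(
    targets: Iterable[Sequence],
    regions: "Iterable[Interval] | None" = None,
    params: "DesignParams | None" = None,
) -> CatcherLibrary:
    """Design a full library over all regions of all targets.

    ``regions=None`` targets each transcript end to end.  Output order is
    deterministic: by target id, then by coordinate.  Duplicate binding
    sites anywhere in the library raise :class:`UniquenessError`.
    """
    params = params or DesignParams()
    targets = list(targets)
    by_id: dict[str, Sequence] = {}
    for t in targets:
        if t.id in by_id:
            raise DesignError(f"duplicate target id {t.id!r}")
        by_id[t.id] = t
    if regions is None:
        region_list = [Interval(t.id, 0, len(t)) for t in targets]
    else:
        region_list = list(regions)
        for r in region_list:
            if r.transcript_id not in by_id:
                raise DesignError(f"region names unknown target {r.transcript_id!r}")
    region_list.sort(key=lambda r: (r.transcript_id, r.start, r.end))
    catchers: list[CatcherStrand] = []
    for region in region_list:
        target = by_id[region.transcript_id]
        for tile in tile_region(target, region, params):
            catchers.append(build_catcher(target, tile, params, screen_against=targets))
    return CatcherLibrary(catchers=catchers, params=params, targets=region_list)


# ---------------------------------------------------------------------------
# off-target screen


def screen_offtargets(
    csl: CatcherLibrary,
    transcriptome: Iterable[Sequence],
    k: "int | None" = None,
    exclude_designed: bool = True,
) -> list[OfftargetHit]:
    """Flag transcripts sharing >= k contiguous bases with a binding site.

    Both strands of each transcript are searched, so a transcript either
    homologous or complementary to a probe is caught — e.g. a readthrough
    transcript embedding a targeted gene segment.  Transcripts a catcher
    was designed against are excluded unless ``exclude_designed`` is off.
    Hits are sorted by shared length, descending.
    """
    k = csl.params.min_offtarget_k if k is None else k
    if k < 8:
        raise DesignError("off-target k must be >= 8")
    hits: list[OfftargetHit] = []
    for catcher in csl:
        for transcript in transcriptome:
            if exclude_designed and transcript.id == catcher.target_interval.transcript_id:
                continue
            m = longest_shared_substring(catcher.binding_site, transcript, both_strands=True)
            if m.length >= k:
                hits.append(
                    OfftargetHit(
                        catcher_name=catcher.name,
                        transcript_id=transcript.id,
                        shared_len=m.length,
                        catcher_interval=Interval(
                            catcher.name, m.a_start, m.a_start + m.length
                        ),
                        transcript_interval=Interval(
                            transcript.id, m.b_start, m.b_start + m.length
                        ),
                        strand=m.strand,
                    )
                )
    hits.sort(key=lambda h: (-h.shared_len, h.catcher_name, h.transcript_id))
    return hits


# ---------------------------------------------------------------------------
# order sheets


_SHEET_COLUMNS = [
    "name",
    "target",
    "start",
    "end",
    "bound_strand",
    "release_site",
    "binding_site",
    "adapter",
    "full_sequence",
]


def order_sheet(csl: CatcherLibrary) -> str:
    """TSV synthesis sheet, one catcher per row."""
    lines = ["\t".join(_SHEET_COLUMNS)]
    for c in csl:
        iv = c.target_interval
        lines.append(
            "\t".join(
                [
                    c.name,
                    iv.transcript_id,
                    str(iv.start),
                    str(iv.end),
                    c.bound_strand,
                    c.release_site.bases if c.release_site else "",
                    c.binding_site.bases,
                    c.adapter.bases,
                    c.full_sequence.bases,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def release_sheet(csl: CatcherLibrary) -> str:
    """TSV of the companion release strands (empty below the header when
    the library was designed without release sites)."""
    lines = ["\t".join(["name", "catcher_name", "sequence"])]
    if csl.params.release_len == 0:
        warnings.warn(
            "library designed with release_len=0: release sheet is empty and "
            "targets can only be recovered by denaturation",
            stacklevel=2,
        )
        return lines[0] + "\n"
    for c in csl:
        rs = design_release_strand(c)
        lines.append("\t".join([rs.sequence.id, rs.catcher_name, rs.sequence.bases]))
    return "\n".join(lines) + "\n"


def read_order_sheet(text_or_path: "str | Path") -> list[CatcherStrand]:
    """Parse an order sheet back into catcher strands (round-trip of
    :func:`order_sheet`).  Accepts a path or the TSV text itself."""
    p = Path(str(text_or_path))
    try:
        is_file = p.is_file()
    except OSError:  # text with newlines is not a valid path on some systems
        is_file = False
    text = p.read_text() if is_file else str(text_or_path)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header != _SHEET_COLUMNS:
        raise ValueError(f"unrecognized order sheet header: {header}")
    catchers = []
    for ln in lines[1:]:
        row = dict(zip(header, ln.split("\t")))
        release = (
            Sequence(f"{row['name']}_toehold", row["release_site"])
            if row["release_site"]
            else None
        )
        c = CatcherStrand(
            name=row["name"],
            target_interval=Interval(row["target"], int(row["start"]), int(row["end"])),
            bound_strand=row["bound_strand"],
            binding_site=Sequence(f"{row['name']}_binding", row["binding_site"]),
            adapter=Sequence("adapter", row["adapter"]),
            release_site=release,
        )
        if c.full_sequence.bases != row["full_sequence"]:
            raise ValueError(f"order sheet row {row['name']} is internally inconsistent")
        catchers.append(c)
    return catchers


def write_library(csl: CatcherLibrary, prefix: "str | Path", release: bool = True) -> list[Path]:
    """Write ``<prefix>.tsv``, ``<prefix>.fasta`` and, with ``release``,
    ``<prefix>.release.tsv`` / ``<prefix>.release.fasta``."""
    prefix = Path(prefix)
    written = []
    tsv = prefix.with_suffix(".tsv")
    tsv.write_text(order_sheet(csl))
    written.append(tsv)
    fasta = prefix.with_suffix(".fasta")
    write_fasta([c.full_sequence for c in csl], fasta)
    written.append(fasta)
    if release:
        rel_tsv = prefix.parent / (prefix.name + ".release.tsv")
        rel_tsv.write_text(release_sheet(csl))
        written.append(rel_tsv)
        if csl.params.release_len > 0:
            rel_fasta = prefix.parent / (prefix.name + ".release.fasta")
            write_fasta([design_release_strand(c).sequence for c in csl], rel_fasta)
            written.append(rel_fasta)
    return written
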