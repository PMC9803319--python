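"""Mock-genome simulation: planted DEL/DUP/INV truth sets under a size-bin design.

The simulation design mirrors a size/type-binned benchmark: each (SV type,
size bin) cell receives a fixed number of planted variants (default 30),
with sizes spanning 100 bp to 280 kbp on log-spaced bins, and the variants are
packed into as many mock genomes as needed so that the total span planted in
any one genome never exceeds a fixed fraction of the reference genome
(default 1%).  Each mock genome is a mutated copy of the reference: deletions
remove their span, tandem duplications insert one extra copy immediately after
the original, and inversions substitute the reverse complement.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .intervals import GenomicInterval, merged_span_length
from .variants import SV_TYPES, StructuralVariant, SvCallSet
from .vcfio import write_sv_bed, write_sv_vcf

__all__ = [
    "BinScheme",
    "MockGenomeSpec",
    "PlacementConfig",
    "TruthSet",
    "build_bin_scheme",
    "pack_bins_into_genomes",
    "place_variants",
    "apply_variants",
    "write_truth",
    "InfeasiblePackingError",
    "PlacementError",
]


class InfeasiblePackingError(ValueError):
    """A planned variant cannot fit any genome under the span budget."""


class PlacementError(RuntimeError):
    """Rejection sampling could not place a variant within the retry cap."""


@dataclass(frozen=True)
class BinScheme:
    """Log-spaced size bins, each holding ``per_bin_count`` SVs of each type.

    Bins are half-open ``[edges[i], edges[i+1])`` except the last, which is
    closed at the top so the maximum size belongs to a bin.
    """

    edges: tuple[int, ...]
    per_bin_count: int = 30

    def __post_init__(self) -> None:
        if len(self.edges) < 2:
            raise ValueError("need at least 2 edges (1 bin)")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly increasing")
        if self.edges[0] < 100:
            raise ValueError("first edge must be >= 100 bp")
        if self.per_bin_count < 1:
            raise ValueError("per_bin_count must be >= 1")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def bin_index(self, size: int) -> int:
        """Bin holding ``size``; half-open lower bins, last bin closed."""
        if size < self.edges[0] or size > self.edges[-1]:
            raise ValueError(f"size {size} outside [{self.edges[0]}, {self.edges[-1]}]")
        for i in range(self.n_bins):
            if size < self.edges[i + 1]:
                return i
        return self.n_bins - 1


def build_bin_scheme(
    min_size: int, max_size: int, n_bins: int, per_bin_count: int = 30
) -> BinScheme:
    """Log-spaced edges from ``min_size`` to ``max_size`` inclusive."""
    if not (1 <= min_size < max_size):
        raise ValueError("need 1 <= min_size < max_size")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    log_lo, log_hi = math.log(min_size), math.log(max_size)
    edges = [
        round(math.exp(log_lo + (log_hi - log_lo) * i / n_bins))
        for i in range(n_bins + 1)
    ]
    edges[0], edges[-1] = min_size, max_size
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("too many bins for this size range (duplicate edges)")
    return BinScheme(edges=tuple(edges), per_bin_count=per_bin_count)


@dataclass
class MockGenomeSpec:
    """The plan for one mock genome: which (type, size, bin) variants it carries."""

    genome_id: str
    planned: list[tuple[str, int, int]] = field(default_factory=list)  # (sv_type, size, bin)

    @property
    def total_span(self) -> int:
        return sum(size for _, size, _ in self.planned)


@dataclass(frozen=True)
class PlacementConfig:
    """Placement constraints for planted variants.

    ``max_fraction`` is the per-genome span budget as a fraction of the total
    reference length.  ``min_gap`` keeps planted variants separated so they are
    scored as distinct events (set 0 to allow adjacency).  ``avoid_n_runs``
    rejects positions intersecting runs of >= 10 Ns.
    """

    max_fraction: float = 0.01
    min_gap: int = 500
    avoid_n_runs: bool = True
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.max_fraction <= 1):
            raise ValueError("max_fraction must be in (0, 1]")
        if self.min_gap < 0:
            raise ValueError("min_gap must be >= 0")


@dataclass
class TruthSet(SvCallSet):
    """Planted variants of one mock genome: pairwise non-overlapping, in-bounds."""

    seed: Optional[int] = None
    reference_id: str = ""

    def __post_init__(self) -> None:
        self.caller = self.caller or "truth"


def _sample_sizes(
    scheme: BinScheme, rng: random.Random
) -> list[tuple[str, int, int]]:
    """All planned (type, size, bin) triples: per_bin_count per (type, bin).

    Sizes are drawn log-uniformly within each bin so every decade of the range
    is represented; the bin's lower edge is always included once per type so
    the boundary sizes are exercised.
    """
    planned = []
    for sv_type in SV_TYPES:
        for b in range(scheme.n_bins):
            lo = scheme.edges[b]
            hi = scheme.edges[b + 1]
            for k in range(scheme.per_bin_count):
                if k == 0:
                    size = lo
                else:
                    u = rng.random()
                    size = int(round(math.exp(math.log(lo) + u * (math.log(hi) - math.log(lo)))))
                    size = min(max(size, lo), hi if b == scheme.n_bins - 1 else hi - 1)
                planned.append((sv_type, size, b))
    return planned


def pack_bins_into_genomes(
    scheme: BinScheme,
    ref_length: int,
    config: PlacementConfig | None = None,
) -> list[MockGenomeSpec]:
    """Pack the full (type, bin) design into mock genomes under the span budget.

    First-fit decreasing by size, with a seeded shuffle breaking size ties, so
    the genome count is near-minimal and the result is deterministic given the
    seed.  Every (type, bin) pair contributes exactly ``per_bin_count`` planned
    variants across the returned specs; every spec's total planted span is at
    most ``max_fraction * ref_length``.
    """
    config = config or PlacementConfig()
    rng = random.Random(config.seed)
    budget = int(config.max_fraction * ref_length)
    planned = _sample_sizes(scheme, rng)
    oversize = [(t, s, b) for t, s, b in planned if s > budget]
    if oversize:
        t, s, b = oversize[0]
        raise InfeasiblePackingError(
            f"a single {t} of {s} bp in bin {b} exceeds the per-genome budget "
            f"of {budget} bp ({config.max_fraction:.2%} of {ref_length} bp)"
        )
    rng.shuffle(planned)  # breaks ties among equal sizes
    planned.sort(key=lambda p: -p[1])  # first-fit decreasing
    specs: list[MockGenomeSpec] = []
    loads: list[int] = []
    for item in planned:
        size = item[1]
        for i, load in enumerate(loads):
            if load + size <= budget:
                specs[i].planned.append(item)
                loads[i] += size
                break
        else:
            specs.append(MockGenomeSpec(genome_id=f"mock{len(specs):03d}", planned=[item]))
            loads.append(size)
    return specs


def _n_run_spans(seq: str, min_run: int = 10) -> list[tuple[int, int]]:
    """Spans of runs of >= min_run consecutive N/n characters."""
    spans = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] in "Nn":
            j = i
            while j < n and seq[j] in "Nn":
                j += 1
            if j - i >= min_run:
                spans.append((i, j))
            i = j
        else:
            i += 1
    return spans


def place_variants(
    reference: Mapping[str, str],
    spec: MockGenomeSpec,
    config: PlacementConfig | None = None,
) -> TruthSet:
    """Assign coordinates to a mock genome's planned variants.

    Positions are drawn uniformly among feasible starts by seeded rejection
    sampling: fully inside a chromosome, separated from already-placed variants
    by at least ``min_gap``, and (by default) not intersecting N-runs.  Larger
    variants are placed first to reduce rejection.  Deterministic given seed.
    """
    config = config or PlacementConfig()
    rng = random.Random(config.seed)
    chrom_names = sorted(reference)
    chrom_lengths = {c: len(reference[c]) for c in chrom_names}
    longest = max(chrom_lengths.values(), default=0)
    n_runs = {
        c: _n_run_spans(reference[c]) if config.avoid_n_runs else []
        for c in chrom_names
    }
    placed: list[StructuralVariant] = []
    placed_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    order = sorted(spec.planned, key=lambda p: (-p[1], p[0], p[2]))
    weights = [chrom_lengths[c] for c in chrom_names]
    for idx, (sv_type, size, b) in enumerate(order):
        if size >= longest:
            raise PlacementError(
                f"{sv_type} of {size} bp does not fit any chromosome (longest {longest} bp)"
            )
        for attempt in range(config.max_retries):
            chrom = rng.choices(chrom_names, weights=weights)[0]
            clen = chrom_lengths[chrom]
            if size >= clen:
                continue
            start = rng.randrange(0, clen - size)
            end = start + size
            lo = start - config.min_gap
            hi = end + config.min_gap
            if any(s < hi and lo < e for s, e in placed_by_chrom[chrom]):
                continue
            if any(s < end and start < e for s, e in n_runs[chrom]):
                continue
            placed.append(
                StructuralVariant(
                    interval=GenomicInterval(chrom, start, end),
                    sv_type=sv_type,
                    id=f"{spec.genome_id}_{sv_type}_bin{b}_{idx}",
                    source="truth",
                )
            )
            placed_by_chrom[chrom].append((start, end))
            break
        else:
            raise PlacementError(
                f"could not place a {size} bp {sv_type} after {config.max_retries} "
                f"attempts; lower the variant density or min_gap"
            )
    placed.sort(key=lambda v: (v.chrom, v.interval.start))
    return TruthSet(
        variants=placed,
        caller="truth",
        sample=spec.genome_id,
        seed=config.seed,
        reference_id=";".join(f"{c}:{chrom_lengths[c]}" for c in chrom_names),
    )


_COMPLEMENT = str.maketrans("ACGTacgtNnRYKMrykm", "TGCAtgcaNnYRMKyrmk")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def apply_variants(
    reference: Mapping[str, str], truth: TruthSet | SvCallSet
) -> dict[str, str]:
    """Mutate reference sequences with the truth set's variants.

    DEL removes ``[start, end)``; tandem DUP inserts one extra copy of
    ``[start, end)`` immediately after ``end``; INV replaces ``[start, end)``
    with its reverse complement.  Variants are applied right-to-left per
    chromosome so the stored coordinates stay valid reference coordinates.
    """
    mutated = dict(reference)
    by_chrom: dict[str, list[StructuralVariant]] = {}
    for v in truth.variants:
        if v.chrom not in reference:
            raise ValueError(f"variant chromosome {v.chrom!r} not in reference")
        if v.interval.end > len(reference[v.chrom]):
            raise ValueError(f"variant {v.id} extends past the end of {v.chrom}")
        by_chrom.setdefault(v.chrom, []).append(v)
    for chrom, vs in by_chrom.items():
        seq = mutated[chrom]
        for v in sorted(vs, key=lambda v: -v.interval.start):
            s, e = v.interval.start, v.interval.end
            if v.sv_type == "DEL":
                seq = seq[:s] + seq[e:]
            elif v.sv_type == "DUP":
                seq = seq[:e] + seq[s:e] + seq[e:]
            elif v.sv_type == "INV":
                seq = seq[:s] + _revcomp(seq[s:e]) + seq[e:]
        mutated[chrom] = seq
    return mutated


def write_truth(
    truth: TruthSet,
    vcf_path: str | Path,
    bed_path: str | Path | None = None,
    contig_lengths: Optional[Mapping[str, int]] = None,
    scheme: BinScheme | None = None,
    config: PlacementConfig | None = None,
) -> None:
    """Write the truth set as VCF (+ optional BED), recording the design in headers."""
    extra = []
    if truth.seed is not None:
        extra.append(f"##svbench_seed={truth.seed}")
    if scheme is not None:
        extra.append(
            f"##svbench_bins={','.join(map(str, scheme.edges))};per_bin={scheme.per_bin_count}"
        )
    if config is not None:
        extra.append(
            f"##svbench_budget=max_fraction={config.max_fraction};min_gap={config.min_gap}"
        )
    write_sv_vcf(truth, vcf_path, contig_lengths=contig_lengths, extra_header_lines=extra)
    if bed_path is not None:
        write_sv_bed(truth, bed_path)


def audit_budget(
    truths: Iterable[TruthSet | SvCallSet], ref_length: int
) -> float:
    """Maximum spanned fraction of the reference over a set of mock genomes."""
    worst = 0.0
    for t in truths:
        span = merged_span_length(v.interval for v in t.variants)
        worst = max(worst, span / ref_length)
    return worst


def random_reference(
    chrom_lengths: Mapping[str, int], seed: int = 0, gc: float = 0.36
) -> dict[str, str]:
    """Generate a random nucleotide reference with the given chromosome lengths.

    Base composition defaults to a GC fraction typical of the C. elegans
    genome.  Intended for toy references in tests and desk-scale benchmarks.
    """
    rng = random.Random(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return {
        chrom: "".join(rng.choices("ACGT", weights=p, k=length))
        for chrom, length in chrom_lengths.items()
    }
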