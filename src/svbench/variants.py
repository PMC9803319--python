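"""Structural-variant data model, callset filters, and overlap deduplication.

Three SV classes are modeled — deletions (DEL), tandem duplications (DUP) and
inversions (INV) — each as a single reference interval.  Callers frequently
emit multiple overlapping predictions of the same type for one event, which
inflates true-positive counts when each is matched against the truth set;
``resolve_overlaps`` collapses every cluster of same-type mutually/transitively
overlapping calls to a single survivor chosen by an ordered criteria list.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .intervals import GenomicInterval

__all__ = [
    "SV_TYPES",
    "StructuralVariant",
    "SvCallSet",
    "FilterConfig",
    "DedupPolicy",
    "sv_length",
    "resolve_overlaps",
]

#: The closed set of supported SV classes; insertions/translocations/breakends
#: are rejected at parse time with a logged skip.
SV_TYPES = ("DEL", "DUP", "INV")


@dataclass(frozen=True)
class StructuralVariant:
    """One DEL/DUP/INV event.

    ``qual`` and ``support`` are optional evidence used by the deduplication
    policy; ``source`` records the caller or sample of origin.
    """

    interval: GenomicInterval
    sv_type: str
    id: str = "."
    qual: Optional[float] = None
    source: str = ""
    support: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(
                f"sv_type must be one of {SV_TYPES}, got {self.sv_type!r}"
            )
        if self.qual is not None and self.qual < 0:
            raise ValueError("qual must be non-negative")

    @property
    def size(self) -> int:
        return self.interval.length

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def sv_length(v: StructuralVariant) -> int:
    """Size of the variant in bp (interval end − start)."""
    return v.interval.length


@dataclass
class SvCallSet:
    """A collection of variants from one caller for one sample."""

    variants: list[StructuralVariant] = field(default_factory=list)
    caller: str = ""
    sample: str = ""
    depth_label: Optional[str] = None

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def of_type(self, sv_type: str) -> list[StructuralVariant]:
        return [v for v in self.variants if v.sv_type == sv_type]


@dataclass(frozen=True)
class FilterConfig:
    """Callset selection criteria: minimum size, FILTER=PASS, optional QUAL cut.

    The defaults retain calls of at least 100 bp whose VCF FILTER field is PASS
    (or missing, per VCF semantics of '.').  ``min_qual`` implements per-depth
    quality cut-offs such as those applied to SVIM output.
    """

    min_size: int = 100
    require_pass: bool = True
    min_qual: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")

    def passes(self, v: StructuralVariant, filter_status: Optional[str] = "PASS") -> bool:
        """filter_status: the record FILTER value; None or '.' counts as passing."""
        if v.size < self.min_size:
            return False
        if self.require_pass and filter_status not in (None, ".", "PASS"):
            return False
        if self.min_qual is not None and (v.qual is None or v.qual < self.min_qual):
            return False
        return True


@dataclass(frozen=True)
class DedupPolicy:
    """Ordered survivor-selection criteria for overlap clusters.

    Each criterion only breaks ties left by the previous one; the terminal
    seeded-random criterion makes the policy total, so exactly one call
    survives per cluster even when no discriminating evidence exists.
    """

    criteria: Sequence[str] = ("qual", "support", "size", "random")
    seed: int = 0

    def __post_init__(self) -> None:
        allowed = {"qual", "support", "size", "random"}
        unknown = set(self.criteria) - allowed
        if unknown:
            raise ValueError(f"unknown dedup criteria: {sorted(unknown)}")


def _overlap_clusters(
    variants: list[StructuralVariant],
) -> list[list[StructuralVariant]]:
    """Connected components under pairwise >=1 bp overlap (same chrom).

    Sweep over sorted intervals: a new component starts whenever a variant's
    start reaches past the running max end of the current component.
    """
    clusters: list[list[StructuralVariant]] = []
    by_chrom: dict[str, list[StructuralVariant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    for chrom in sorted(by_chrom):
        vs = sorted(by_chrom[chrom], key=lambda v: (v.interval.start, v.interval.end))
        cur: list[StructuralVariant] = [vs[0]]
        max_end = vs[0].interval.end
        for v in vs[1:]:
            if v.interval.start < max_end:
                cur.append(v)
                max_end = max(max_end, v.interval.end)
            else:
                clusters.append(cur)
                cur = [v]
                max_end = v.interval.end
        clusters.append(cur)
    return clusters


def resolve_overlaps(calls: SvCallSet, policy: DedupPolicy | None = None) -> SvCallSet:
    """Collapse same-type overlap clusters to one survivor each.

    Clusters are connected components of the >=1 bp-overlap relation among
    variants of a single type (transitive chains yield one survivor).
    Different-type overlaps are untouched.  Deterministic given the policy
    seed; idempotent, since the output contains no same-type overlapping pair.
    """
    policy = policy or DedupPolicy()
    rng = random.Random(policy.seed)
    survivors: list[StructuralVariant] = []
    for sv_type in SV_TYPES:
        typed = calls.of_type(sv_type)
        if not typed:
            continue
        for cluster in _overlap_clusters(typed):
            if len(cluster) == 1:
                survivors.append(cluster[0])
                continue
            # Seeded shuffle supplies the terminal random tie-break; the stable
            # sort then applies the ordered criteria on top of it.
            candidates = list(cluster)
            rng.shuffle(candidates)

            def sort_key(v: StructuralVariant) -> tuple:
                key = []
                for crit in policy.criteria:
                    if crit == "qual":
                        key.append(-(v.qual if v.qual is not None else float("-inf")))
                    elif crit == "support":
                        key.append(-(v.support if v.support is not None else float("-inf")))
                    elif crit == "size":
                        key.append(-v.size)
                    # "random" is the shuffle order itself
                return tuple(key)

            candidates.sort(key=sort_key)
            survivors.append(candidates[0])
    survivors.sort(key=lambda v: (v.chrom, v.interval.start, v.interval.end, v.sv_type))
    return replace_variants(calls, survivors)


def replace_variants(calls: SvCallSet, variants: Iterable[StructuralVariant]) -> SvCallSet:
    return SvCallSet(
        variants=list(variants),
        caller=calls.caller,
        sample=calls.sample,
        depth_label=calls.depth_label,
    )
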