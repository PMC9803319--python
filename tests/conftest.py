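"""Shared fixtures and independent per-base oracles.

The oracles represent interval coverage as explicit boolean base masks
(numpy arrays over a small genome) so that overlap, reciprocal overlap,
Jaccard, and TP/FP/FN classification can be recomputed by brute force,
independently of the package's sorted-run implementations.
"""

from __future__ import annotations

import random

import numpy as np
import pytest

from svbench import GenomicInterval, StructuralVariant, SvCallSet


def iv(chrom: str, start: int, end: int) -> GenomicInterval:
    return GenomicInterval(chrom, start, end)


def sv(chrom, start, end, sv_type="DEL", id=".", qual=None, support=None, source=""):
    return StructuralVariant(
        interval=GenomicInterval(chrom, start, end),
        sv_type=sv_type, id=id, qual=qual, support=support, source=source,
    )


# ---------------------------------------------------------------- oracles

def mask(intervals, chroms: dict[str, int]) -> dict[str, np.ndarray]:
    """Boolean base-coverage masks per chromosome."""
    m = {c: np.zeros(n, dtype=bool) for c, n in chroms.items()}
    for i in intervals:
        m[i.chrom][i.start:i.end] = True
    return m


def oracle_overlap_length(a, b, chroms) -> int:
    ma, mb = mask([a], chroms), mask([b], chroms)
    return int(sum((ma[c] & mb[c]).sum() for c in chroms))


def oracle_reciprocal(a, b, chroms) -> float:
    ovl = oracle_overlap_length(a, b, chroms)
    if ovl == 0:
        return 0.0
    return min(ovl / a.length, ovl / b.length)


def oracle_merged_span(intervals, chroms) -> int:
    m = mask(intervals, chroms)
    return int(sum(m[c].sum() for c in chroms))


def oracle_jaccard(set_a, set_b, chroms) -> float:
    ma, mb = mask(set_a, chroms), mask(set_b, chroms)
    inter = sum((ma[c] & mb[c]).sum() for c in chroms)
    union = sum((ma[c] | mb[c]).sum() for c in chroms)
    return float(inter / union) if union else 0.0


def oracle_classify(calls, truth, min_recip, chroms):
    """Brute-force O(calls x truth) same-type reciprocal-overlap matching."""
    tp = fp = 0
    detected = set()
    for c in calls:
        hit = False
        for j, t in enumerate(truth):
            if c.sv_type != t.sv_type:
                continue
            if oracle_reciprocal(c.interval, t.interval, chroms) >= min_recip:
                hit = True
                detected.add(j)
        tp += hit
        fp += not hit
    fn = len(truth) - len(detected)
    return tp, fp, fn


def random_intervals(rng: random.Random, n: int, chroms: dict[str, int],
                     max_len: int = 500) -> list[GenomicInterval]:
    out = []
    names = sorted(chroms)
    for _ in range(n):
        c = rng.choice(names)
        ln = rng.randint(1, max_len)
        s = rng.randrange(0, chroms[c] - ln)
        out.append(GenomicInterval(c, s, s + ln))
    return out


def nonoverlapping_truth(rng: random.Random, n: int, chrom: str, chrom_len: int,
                         min_size=100, max_size=1000, gap=50,
                         types=("DEL", "DUP", "INV")) -> SvCallSet:
    """Evenly laid-out non-overlapping truth variants for recovery tests."""
    variants = []
    pos = 0
    for i in range(n):
        size = rng.randint(min_size, max_size)
        if pos + size + gap > chrom_len:
            break
        variants.append(sv(chrom, pos, pos + size, rng.choice(types), id=f"t{i}"))
        pos += size + gap
    return SvCallSet(variants=variants, caller="truth")


@pytest.fixture
def toy_chroms() -> dict[str, int]:
    return {"I": 10_000, "II": 8_000}
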