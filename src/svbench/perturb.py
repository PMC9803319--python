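"""Synthetic caller: perturb a truth set into a callset with known error rates.

Real SV callers miss events, invent events, misplace breakpoints, and sometimes
report one event as several fragments spanning it.  ``perturb_truth`` emulates
those four failure modes with controlled rates so the evaluation stack can be
exercised end-to-end and its measured precision/recall checked against the
rates that generated the calls.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Mapping

from .intervals import GenomicInterval
from .variants import StructuralVariant, SvCallSet

__all__ = ["PerturbationConfig", "perturb_truth", "FpPlacementError"]


class FpPlacementError(RuntimeError):
    """False-positive placement exceeded the retry cap."""


@dataclass(frozen=True)
class PerturbationConfig:
    """Error model of the synthetic caller.

    fn_rate
        Probability each truth variant is dropped (a false negative).
    fp_rate
        Expected fraction of the emitted calls that are novel false events.
    jitter_sd
        Standard deviation (bp) of independent Gaussian shifts applied to each
        breakpoint of surviving calls, rounded to integers and clamped to keep
        size >= 1 and the call inside its chromosome.
    split_prob
        Probability a surviving call is emitted as two abutting same-type
        sub-calls partitioning its span (the fragmented-call failure mode).
    """

    fn_rate: float = 0.0
    fp_rate: float = 0.0
    jitter_sd: float = 0.0
    split_prob: float = 0.0
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        for name in ("fn_rate", "fp_rate", "split_prob"):
            val = getattr(self, name)
            if not (0 <= val < 1):
                raise ValueError(f"{name} must be in [0, 1), got {val}")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def _jitter(
    v: StructuralVariant,
    rng: random.Random,
    sd: float,
    chrom_len: int,
) -> StructuralVariant:
    start = v.interval.start + round(rng.gauss(0, sd))
    end = v.interval.end + round(rng.gauss(0, sd))
    start = max(0, min(start, chrom_len - 1))
    end = max(start + 1, min(end, chrom_len))
    return StructuralVariant(
        interval=GenomicInterval(v.chrom, start, end),
        sv_type=v.sv_type,
        id=v.id,
        qual=v.qual,
        source=v.source,
        support=v.support,
    )


def perturb_truth(
    truth: SvCallSet,
    config: PerturbationConfig,
    reference_lengths: Mapping[str, int],
    caller: str = "mock",
) -> SvCallSet:
    """Emit a synthetic callset derived from ``truth`` under the error model.

    Each truth variant is independently dropped with ``fn_rate``; survivors get
    Gaussian breakpoint jitter and, with ``split_prob``, are split into two
    abutting halves.  False positives with types and sizes resampled from the
    truth's empirical distribution are added at random positions that overlap
    neither the truth nor each other, in a count that makes the expected FP
    fraction of the output equal ``fp_rate``.  Deterministic given the seed.
    An all-zero configuration returns calls identical to the truth.
    """
    for v in truth.variants:
        if v.chrom not in reference_lengths:
            raise ValueError(f"no reference length for chromosome {v.chrom!r}")
    rng = random.Random(config.seed)
    emitted: list[StructuralVariant] = []
    survivors = 0
    for v in truth.variants:
        if rng.random() < config.fn_rate:
            continue
        survivors += 1
        call = v
        if config.jitter_sd > 0:
            call = _jitter(v, rng, config.jitter_sd, reference_lengths[v.chrom])
        if config.split_prob > 0 and call.size >= 2 and rng.random() < config.split_prob:
            mid = call.interval.start + call.size // 2
            for part, (s, e) in enumerate(
                [(call.interval.start, mid), (mid, call.interval.end)]
            ):
                emitted.append(
                    StructuralVariant(
                        interval=GenomicInterval(call.chrom, s, e),
                        sv_type=call.sv_type,
                        id=f"{call.id}_part{part + 1}",
                        qual=call.qual,
                        source=caller,
                    )
                )
        else:
            emitted.append(
                StructuralVariant(
                    interval=call.interval,
                    sv_type=call.sv_type,
                    id=call.id,
                    qual=call.qual,
                    source=caller,
                    support=call.support,
                )
            )

    # n_fp true-call-free events so that n_fp / (survivors + n_fp) ~= fp_rate.
    if config.fp_rate > 0 and truth.variants:
        n_fp = round(survivors * config.fp_rate / (1 - config.fp_rate))
        sizes_types = [(v.sv_type, v.size) for v in truth.variants]
        occupied: dict[str, list[tuple[int, int]]] = {}
        for v in truth.variants:
            occupied.setdefault(v.chrom, []).append(
                (v.interval.start, v.interval.end)
            )
        chroms = sorted(reference_lengths)
        weights = [reference_lengths[c] for c in chroms]
        for k in range(n_fp):
            sv_type, size = rng.choice(sizes_types)
            for attempt in range(config.max_retries):
                chrom = rng.choices(chroms, weights=weights)[0]
                clen = reference_lengths[chrom]
                if size >= clen:
                    continue
                start = rng.randrange(0, clen - size)
                end = start + size
                if any(s < end and start < e for s, e in occupied.get(chrom, [])):
                    continue
                emitted.append(
                    StructuralVariant(
                        interval=GenomicInterval(chrom, start, end),
                        sv_type=sv_type,
                        id=f"fp_{k}",
                        source=caller,
                    )
                )
                occupied.setdefault(chrom, []).append((start, end))
                break
            else:
                raise FpPlacementError(
                    f"could not place false positive of {size} bp after "
                    f"{config.max_retries} attempts"
                )

    emitted.sort(key=lambda v: (v.chrom, v.interval.start, v.interval.end))
    return SvCallSet(variants=emitted, caller=caller, sample=truth.sample)
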