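"""Genetic sexing from X-chromosomal heterozygosity plus a Y presence marker.

Males carry one X, so an array reports every X marker as homozygous and
their X-inbreeding statistic F sits near 1; outbred females are heterozygous
at a share of the X markers and F sits near 0.  A sample is called MALE only
when the Y marker amplified AND the X statistic agrees, FEMALE only when the
Y is absent AND the X statistic is low — positive confirmation for both
sexes.  Conflicting indicators (Y present with heterozygous X) are the
signature of a male+female mixture, common in over-marked urine, and are
flagged rather than called.  Inbred females that happen to be homozygous at
every X marker cannot be separated from males by the X statistic alone; with
no Y they come out UNCERTAIN, never FEMALE-by-default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, call_alleles, is_het

MALE = "MALE"
FEMALE = "FEMALE"
UNCERTAIN = "UNCERTAIN"


@dataclass
class SexConfig:
    """Thresholds on the X-homozygosity statistic F and the Y rule."""

    f_male_min: float = 0.8
    f_female_max: float = 0.2
    min_x_typed: int = 5
    known_sex_wins: bool = True

    def __post_init__(self) -> None:
        if not self.f_female_max < self.f_male_min:
            raise ValueError("need f_female_max < f_male_min")


@dataclass
class SexCall:
    sample_id: str
    x_f: float  # NaN when too few X markers typed
    n_x_typed: int
    y_detected: bool
    call: str
    conflict_flag: bool = False
    note: str = ""


def x_inbreeding_f(
    sample_calls: Mapping[str, str] | Sequence[tuple[str, str]],
    x_freqs: Mapping[str, float],
    min_x_typed: int = 5,
) -> tuple[float, int]:
    """Method-of-moments X inbreeding/homozygosity statistic.

    F = (O_hom - E_hom) / (L - E_hom) with E_hom = sum over typed loci of
    (1 - 2 p q), p taken from reference female allele frequencies.  Returns
    (F, number of typed X loci); F is NaN below ``min_x_typed``.
    """
    items = dict(sample_calls).items()
    o_hom = 0
    e_hom = 0.0
    n_typed = 0
    for mid, call in items:
        if call == MISSING or mid not in x_freqs:
            continue
        p = x_freqs[mid]
        n_typed += 1
        e_hom += 1.0 - 2.0 * p * (1.0 - p)
        if not is_het(call):
            o_hom += 1
    if n_typed < min_x_typed:
        return float("nan"), n_typed
    denom = n_typed - e_hom
    if denom <= 0:
        return float("nan"), n_typed
    return (o_hom - e_hom) / denom, n_typed


def call_sex(
    sample_id: str,
    x_f: float,
    n_x_typed: int,
    y_detected: bool,
    config: SexConfig | None = None,
    known_sex: str | None = None,
) -> SexCall:
    """Combine the X statistic and Y detection into a sex call.

    MALE needs Y present and a high (or undefined) F; FEMALE needs Y absent
    and a low F.  A detected Y whose X statistic fails to confirm a male is
    a pair of conflicting indicators — a male cannot be heterozygous on the
    X — and is the cross-contamination signature, so it is flagged and left
    UNCERTAIN.  Y absent with a high F is the all-homozygous-female /
    failed-Y ambiguity and stays UNCERTAIN without a flag.  A recorded
    physiological sex wins over the genetic call (conflicts still flagged)
    when configured.
    """
    cfg = config or SexConfig()
    undefined = math.isnan(x_f)
    conflict = False
    if y_detected:
        if undefined or x_f >= cfg.f_male_min:
            call = MALE
        else:
            call, conflict = UNCERTAIN, True  # Y present, X not male-like
    else:
        if not undefined and x_f <= cfg.f_female_max:
            call = FEMALE
        else:
            call = UNCERTAIN  # includes the inbred all-hom female

    note = ""
    if known_sex in (MALE, FEMALE):
        if call in (MALE, FEMALE) and call != known_sex:
            conflict = True
            note = f"genetic call {call} conflicts with recorded sex {known_sex}"
        if cfg.known_sex_wins:
            call = known_sex
    if conflict and not (known_sex and cfg.known_sex_wins):
        call = UNCERTAIN
    return SexCall(
        sample_id=sample_id,
        x_f=x_f,
        n_x_typed=n_x_typed,
        y_detected=y_detected,
        call=call,
        conflict_flag=conflict,
        note=note,
    )


def sex_table(
    table,
    x_marker_ids: Sequence[str],
    y_marker_id: str | None,
    x_freqs: Mapping[str, float],
    config: SexConfig | None = None,
    known_sex: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Sex-call every sample of a GenotypeTable; returns a tidy frame."""
    cfg = config or SexConfig()
    rows = []
    x_set = [m for m in x_marker_ids if m in set(table.marker_ids)]
    for sid in table.sample_ids:
        calls = {m: table.get(sid, m) for m in x_set}
        f, n_typed = x_inbreeding_f(calls, x_freqs, cfg.min_x_typed)
        y_det = (
            y_marker_id in set(table.marker_ids)
            and table.get(sid, y_marker_id) != MISSING
        )
        sc = call_sex(sid, f, n_typed, y_det, cfg,
                      known_sex.get(sid) if known_sex else None)
        rows.append(
            {"sample_id": sid, "x_f": sc.x_f, "n_x_typed": sc.n_x_typed,
             "y_detected": sc.y_detected, "call": sc.call,
             "conflict_flag": sc.conflict_flag, "note": sc.note}
        )
    return pd.DataFrame(rows)


def tune_thresholds(
    observations: Sequence[tuple[float, bool, str]],
    grid: Sequence[float] | None = None,
    config: SexConfig | None = None,
) -> tuple[SexConfig, pd.DataFrame]:
    """Grid-search (f_male_min, f_female_max) for zero mis-calls on knowns.

    ``observations`` are (x_f, y_detected, known_sex) triples.  Among
    configurations with no mis-called known sample, the one calling the most
    samples wins; ties prefer the widest UNCERTAIN band (most conservative).
    If nothing achieves zero mis-calls the most conservative grid point is
    returned with the conflict set.  The returned frame lists knowns that
    remain uncalled or conflicted under the chosen thresholds.
    """
    if not observations:
        raise ValueError("threshold tuning needs at least one known-sex sample")
    base = config or SexConfig()
    grid = list(grid) if grid is not None else [round(x, 2) for x in
                                                np.arange(0.05, 1.0, 0.05)]

    def evaluate(f_hi: float, f_lo: float) -> tuple[int, int, list[int]]:
        cfg = SexConfig(f_male_min=f_hi, f_female_max=f_lo,
                        min_x_typed=base.min_x_typed)
        n_called = n_wrong = 0
        wrong_idx = []
        for idx, (xf, y, known) in enumerate(observations):
            sc = call_sex("_", xf, base.min_x_typed, y, cfg)
            if sc.call in (MALE, FEMALE):
                n_called += 1
                if sc.call != known:
                    n_wrong += 1
                    wrong_idx.append(idx)
        return n_called, n_wrong, wrong_idx

    best = None
    for f_lo, f_hi in itertools.product(grid, grid):
        if f_lo >= f_hi:
            continue
        n_called, n_wrong, wrong = evaluate(f_hi, f_lo)
        band = f_hi - f_lo
        key = (n_wrong == 0, n_called if n_wrong == 0 else -n_wrong, band)
        if best is None or key > best[0]:
            best = (key, f_hi, f_lo, wrong)
    assert best is not None
    (zero_ok, _, _), f_hi, f_lo, wrong = best
    if not zero_ok:
        # nothing separates the knowns: fall back to the widest band
        f_hi, f_lo = max(grid), min(grid)
        _, _, wrong = evaluate(f_hi, f_lo)

    cfg = SexConfig(f_male_min=f_hi, f_female_max=f_lo,
                    min_x_typed=base.min_x_typed)
    rows = []
    for idx, (xf, y, known) in enumerate(observations):
        sc = call_sex(str(idx), xf, base.min_x_typed, y, cfg)
        if sc.call != known or idx in wrong:
            rows.append({"index": idx, "x_f": xf, "y_detected": y,
                         "known_sex": known, "called": sc.call,
                         "conflict": sc.conflict_flag or idx in wrong})
    return cfg, pd.DataFrame(rows, columns=["index", "x_f", "y_detected",
                                            "known_sex", "called", "conflict"])
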