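"""Molecular dating of provirus integrations from LTR-LTR divergence.

At integration the two long terminal repeats of a provirus are identical;
they then accumulate substitutions independently, so their divergence D
grows at twice the host's neutral rate and the integration time is

    T = (D / R) / 2

with R the genomic substitution rate in substitutions per site per year.
D may be the raw p-distance over ungapped aligned columns (the default,
most conservative reading of "nucleotide divergence") or its JC69
correction -(3/4) ln(1 - (4/3) p). Loci without a detectable LTR pair are
reported as explicitly undatable — a missing pair never yields a fabricated
estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import binomtest

from .annotate import LTRPair

#: Published neutral-rate presets (substitutions / site / year).
RATE_PRESETS: dict[str, float] = {
    # neutral substitution rate estimated for ancestral ruminant lineages
    "ruminant_ancestral": 1.5e-9,
}

MODELS = ("p-distance", "JC69")


class DatingError(ValueError):
    pass


@dataclass
class DatingParams:
    R: float = RATE_PRESETS["ruminant_ancestral"]
    model: str = "p-distance"
    ci_confidence: float | None = None  # e.g. 0.95 to attach a binomial CI

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise DatingError("substitution rate R must be positive")
        if self.model not in MODELS:
            raise DatingError(f"model must be one of {MODELS}")


@dataclass
class DatingResult:
    locus_id: str
    status: str  # 'dated' or 'undatable'
    D: float | None = None
    T_years: float | None = None
    T_mya: float | None = None
    R: float | None = None
    model: str | None = None
    ltr_aligned_length: int | None = None
    mismatches: int | None = None
    ci_low_years: float | None = None
    ci_high_years: float | None = None


def correct_distance(p: float, model: str) -> float:
    """p-distance -> divergence under the requested model."""
    if p < 0:
        raise DatingError("p-distance cannot be negative")
    if model == "p-distance":
        return p
    if model == "JC69":
        if p >= 0.75:
            raise DatingError(f"p = {p:.3f} is saturated under JC69 (p >= 0.75)")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    raise DatingError(f"unknown model {model!r}")


def ltr_divergence(ltr_pair: LTRPair, model: str = "p-distance") -> float:
    """Divergence D between the two LTRs of a pair.

    p-distance is mismatches over ungapped aligned columns (indel columns
    are excluded from the denominator); JC69 corrects for multiple hits.
    """
    if ltr_pair.aligned_length <= 0:
        raise DatingError("LTR pair has no aligned columns")
    return correct_distance(ltr_pair.p_distance, model)


def estimate_integration_time(D: float, params: DatingParams,
                              locus_id: str = "") -> DatingResult:
    """T = (D / R) / 2, reported in years and millions of years.

    The identity holds exactly on the reporting path; only display formatting
    rounds.
    """
    if D < 0:
        raise DatingError("divergence D cannot be negative")
    t_years = (D / params.R) / 2.0
    return DatingResult(
        locus_id=locus_id, status="dated", D=D,
        T_years=t_years, T_mya=t_years / 1e6,
        R=params.R, model=params.model,
    )


def date_ltr_pair(ltr_pair: LTRPair, params: DatingParams,
                  locus_id: str = "") -> DatingResult:
    """Full path from an LTR pair to a dated result, with optional CI.

    The confidence interval treats the mismatch count as binomial over the
    ungapped aligned columns and pushes its bounds through the same model
    correction and clock relation; it is an extension beyond the point
    estimate and is off unless ``params.ci_confidence`` is set.
    """
    p = ltr_pair.p_distance
    D = correct_distance(p, params.model)
    result = estimate_integration_time(D, params, locus_id=locus_id)
    result.ltr_aligned_length = ltr_pair.aligned_length
    result.mismatches = ltr_pair.mismatches
    if params.ci_confidence is not None and ltr_pair.aligned_length > 0:
        ci = binomtest(ltr_pair.mismatches, ltr_pair.aligned_length).proportion_ci(
            confidence_level=params.ci_confidence)
        lo = correct_distance(ci.low, params.model)
        hi_p = min(ci.high, 0.7499) if params.model == "JC69" else ci.high
        hi = correct_distance(hi_p, params.model)
        result.ci_low_years = (lo / params.R) / 2.0
        result.ci_high_years = (hi / params.R) / 2.0
    return result


def date_all(ltr_pairs: Mapping[str, LTRPair | None],
             params: DatingParams) -> list[DatingResult]:
    """Date every locus that has an LTR pair; report the rest as undatable.

    Output order is deterministic by locus id.
    """
    results = []
    for locus_id in sorted(ltr_pairs):
        pair = ltr_pairs[locus_id]
        if pair is None or pair.aligned_length == 0:
            results.append(DatingResult(locus_id=locus_id, status="undatable"))
        else:
            results.append(date_ltr_pair(pair, params, locus_id=locus_id))
    return results


def results_to_frame(results: Sequence[DatingResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "locus_id": r.locus_id, "status": r.status,
        "ltr_aligned_length": r.ltr_aligned_length, "mismatches": r.mismatches,
        "D": r.D, "model": r.model, "R": r.R,
        "T_years": r.T_years, "T_mya": r.T_mya,
        "ci_low_years": r.ci_low_years, "ci_high_years": r.ci_high_years,
    } for r in results])


def write_report(results: Sequence[DatingResult], tsv_path: str | Path | None = None,
                 json_path: str | Path | None = None) -> pd.DataFrame:
    df = results_to_frame(results)
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(df.to_json(orient="records", indent=1))
    return df
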