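"""Worked-example cohort specs reconstructed from the published tables.

The source study prints cohort sizes and percentage rates, not counts,
so each fixture back-solves the integer count k from the printed rate r
and cohort size N: k is the integer with round(100·k/N, d) == r at the
printed precision d.  :func:`back_solve_count` scans k = 0..N; when
several k round to the printed value the smallest is used and a warning
is logged; when none does, the rate cannot be embedded and is rejected.

Patients not accounted for by printed rates are filled with pathways
disjoint from the documented ones, so the documented rates are exactly
reproducible by the pipeline while cohort sizes match the published
totals (STARR: 77 amputation / 5504 non-amputation; All of Us: 176 /
4085).
"""

from __future__ import annotations

import logging

from .model import Comorbidity, OutcomeLabel, TreatmentCode, percentage
from .synthetic import AttributeTemplate, PathwayAllocation, SyntheticSpec

logger = logging.getLogger(__name__)

A = TreatmentCode.ANTIPLATELET
L = TreatmentCode.LIPID_LOWERING
SC = TreatmentCode.SMOKING_CESSATION
ET = TreatmentCode.EXERCISE_THERAPY
ER = TreatmentCode.ENDOVASCULAR_REVASCULARIZATION
RS = TreatmentCode.REVASCULARIZATION_SURGERY

AMP = OutcomeLabel.AMPUTATION
NON = OutcomeLabel.NON_AMPUTATION


def back_solve_count(printed_rate: float, cohort_size: int, decimals: int = 2) -> int:
    """Smallest integer k with round(100·k/cohort_size, decimals) equal to
    the printed rate (half away from zero).  Raises when no k matches."""
    matches = [
        k
        for k in range(cohort_size + 1)
        if abs(percentage(k, cohort_size, decimals) - printed_rate) < 1e-9
    ]
    if not matches:
        raise ValueError(
            f"no integer count yields {printed_rate}% of {cohort_size} at {decimals} dp"
        )
    if len(matches) > 1:
        logger.warning(
            "ambiguous back-solve: %s%% of %d matches k in %s; using smallest",
            printed_rate, cohort_size, matches,
        )
    return matches[0]


def _starr_amputation_table2(seed: int) -> SyntheticSpec:
    n = 77  # published STARR amputation cohort size
    counts = {
        (A, L, ER): back_solve_count(7.79, n),        # printed 7.79  -> 6
        (A, RS, L): back_solve_count(5.19, n),        # printed 5.19  -> 4
        (RS, L, A): back_solve_count(2.6, n, 1),      # printed 2.6   -> 2
        (ER, L): back_solve_count(1.3, n, 1),         # printed 1.3   -> 1
        (A, L): back_solve_count(25.97, n),           # printed 25.97 -> 20
        (L,): back_solve_count(15.58, n),             # printed 15.58 -> 12
    }
    filler = n - sum(counts.values())  # 32 patients on undocumented pathways
    allocations = [PathwayAllocation(steps, AMP, k) for steps, k in counts.items()]
    allocations += [
        PathwayAllocation((A,), AMP, 10),
        PathwayAllocation((SC,), AMP, 8),
        PathwayAllocation((ET,), AMP, 8),
        PathwayAllocation((ER,), AMP, filler - 26),
    ]
    return SyntheticSpec(dataset_label="starr_amp", allocations=allocations, seed=seed)


def _allofus_table4(seed: int) -> SyntheticSpec:
    n = 176  # published All of Us amputation cohort size
    counts = {
        (ER,): back_solve_count(13.6, n, 1),          # printed 13.6 -> 24
        (ER, RS): back_solve_count(6.25, n),          # printed 6.25 -> 11
        (L, A, ER): back_solve_count(3.98, n),        # printed 3.98 -> 7
        (A, L, ER): back_solve_count(2.84, n),        # printed 2.84 -> 5
    }
    filler = n - sum(counts.values())
    allocations = [PathwayAllocation(steps, AMP, k) for steps, k in counts.items()]
    allocations += [
        PathwayAllocation((A,), AMP, 40),
        PathwayAllocation((L,), AMP, 30),
        PathwayAllocation((A, L), AMP, 30),
        PathwayAllocation((L, A), AMP, filler - 100),
    ]
    return SyntheticSpec(dataset_label="allofus_amp", allocations=allocations, seed=seed)


def _starr_table6_nonamp(seed: int) -> SyntheticSpec:
    n = 5504  # published STARR non-amputation cohort size
    counts = {
        (A, L): back_solve_count(32.29, n),           # printed 32.29 -> 1777
        (L, A): back_solve_count(24.1, n, 1),         # printed 24.1
        (L,): back_solve_count(16.8, n, 1),           # printed 16.8
        (A,): back_solve_count(10.2, n, 1),           # printed 10.2
    }
    filler = n - sum(counts.values())
    allocations = [PathwayAllocation(steps, NON, k) for steps, k in counts.items()]
    allocations += [
        PathwayAllocation((ET,), NON, filler // 2),
        PathwayAllocation((SC,), NON, filler - filler // 2),
    ]
    return SyntheticSpec(dataset_label="starr_nonamp", allocations=allocations, seed=seed)


def _starr_hypertension(seed: int) -> SyntheticSpec:
    """Mixed cohort: the published hypertension stratum (56 amputation /
    3812 non-amputation) plus non-hypertensive distractors completing the
    full STARR cohort (77 / 5504)."""
    htn = AttributeTemplate(comorbidities=frozenset({Comorbidity.HYPERTENSION}))
    no_htn = AttributeTemplate(comorbidities=frozenset())
    n_amp, n_non = 56, 3812
    amp_counts = {
        (RS, L, A, ER): back_solve_count(1.79, n_amp),  # printed 1.79 -> 1
        (A, RS, L): back_solve_count(7.14, n_amp),      # printed 7.14 -> 4
        (A, L, ER): back_solve_count(7.14, n_amp),      # printed 7.14 -> 4
    }
    amp_filler = n_amp - sum(amp_counts.values())
    non_counts = {
        (A, L): back_solve_count(33, n_non, 0),         # printed 33%
        (L, A): back_solve_count(27, n_non, 0),         # printed 27%
        (L,): back_solve_count(15, n_non, 0),           # printed 15%
    }
    non_filler = n_non - sum(non_counts.values())
    allocations = [
        PathwayAllocation(steps, AMP, k, attributes=htn) for steps, k in amp_counts.items()
    ]
    allocations += [
        PathwayAllocation((A, L), AMP, 15, attributes=htn),
        PathwayAllocation((L,), AMP, 12, attributes=htn),
        PathwayAllocation((A,), AMP, 10, attributes=htn),
        PathwayAllocation((ER,), AMP, amp_filler - 37, attributes=htn),
    ]
    allocations += [
        PathwayAllocation(steps, NON, k, attributes=htn) for steps, k in non_counts.items()
    ]
    allocations += [
        PathwayAllocation((A,), NON, 400, attributes=htn),
        PathwayAllocation((ET,), NON, non_filler - 400 - (non_filler - 400) // 2, attributes=htn),
        PathwayAllocation((SC,), NON, (non_filler - 400) // 2, attributes=htn),
    ]
    # Non-hypertensive distractors: 77-56 amputations, 5504-3812 others.
    allocations += [
        PathwayAllocation((A, L), AMP, 5, attributes=no_htn),
        PathwayAllocation((L,), AMP, 5, attributes=no_htn),
        PathwayAllocation((A,), AMP, 5, attributes=no_htn),
        PathwayAllocation((ET,), AMP, 6, attributes=no_htn),
        PathwayAllocation((ET,), NON, 846, attributes=no_htn),
        PathwayAllocation((SC,), NON, 846, attributes=no_htn),
    ]
    return SyntheticSpec(dataset_label="starr_htn", allocations=allocations, seed=seed)


def _starr_age_le50(seed: int) -> SyntheticSpec:
    """Mixed cohort: the published age ≤ 50 stratum (3 amputation / 265
    non-amputation) plus older distractors completing 77 / 5504."""
    young = AttributeTemplate(age=(30, 50))
    old = AttributeTemplate(age=(51, 90))
    n_non = 265
    young_non = {
        (L,): back_solve_count(18.49, n_non),           # printed 18.49 -> 49
        (A, L): back_solve_count(17.36, n_non),         # printed 17.36 -> 46
        (A, ER): back_solve_count(5.28, n_non),         # printed 5.28  -> 14
    }
    young_filler = n_non - sum(young_non.values())
    allocations = [
        # printed 66.67% -> 2 of 3; printed 33.33% -> 1 of 3
        PathwayAllocation((A, L), AMP, back_solve_count(66.67, 3), attributes=young),
        PathwayAllocation((A,), AMP, back_solve_count(33.33, 3), attributes=young),
    ]
    allocations += [
        PathwayAllocation(steps, NON, k, attributes=young) for steps, k in young_non.items()
    ]
    allocations += [
        PathwayAllocation((A,), NON, 60, attributes=young),
        PathwayAllocation((SC,), NON, (young_filler - 60) // 2, attributes=young),
        PathwayAllocation((ET,), NON, young_filler - 60 - (young_filler - 60) // 2,
                          attributes=young),
    ]
    # Older distractors: published >50 stratum sizes (74 / 5239).
    allocations += [
        PathwayAllocation((A, L), AMP, 20, attributes=old),
        PathwayAllocation((L,), AMP, 15, attributes=old),
        PathwayAllocation((A, L, ER), AMP, 6, attributes=old),
        PathwayAllocation((ET,), AMP, 33, attributes=old),
        PathwayAllocation((A, L), NON, 1700, attributes=old),
        PathwayAllocation((L, A), NON, 1300, attributes=old),
        PathwayAllocation((L,), NON, 900, attributes=old),
        PathwayAllocation((A,), NON, 539, attributes=old),
        PathwayAllocation((ET,), NON, 800, attributes=old),
    ]
    return SyntheticSpec(dataset_label="starr_age", allocations=allocations, seed=seed)


_FIXTURES = {
    "starr_amputation_table2": _starr_amputation_table2,
    "allofus_table4": _allofus_table4,
    "starr_table6_nonamp": _starr_table6_nonamp,
    "starr_hypertension": _starr_hypertension,
    "starr_age_le50": _starr_age_le50,
}


def available_fixtures() -> list[str]:
    return sorted(_FIXTURES)


def paper_fixture(name: str, seed: int = 0) -> SyntheticSpec:
    """Return the named worked-example spec with the given seed."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {available_fixtures()}"
        ) from None
    spec = builder(seed)
    spec.validate()
    return spec
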