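"""Reference cohort data: aggregate counts and a marginal-matching reconstruction.

The package ships the aggregate region x node-field contingency counts from an
869-tumour (861-patient) lymphoscintigraphy/SPECT-CT breast cohort, already
reflected to the left side.  ``reference_contingency`` returns those counts.

Because the record-level drainage sets behind the aggregate table are not
public, ``reconstruct_reference_cohort`` builds a deterministic synthetic
cohort of 869 tumour records whose *marginal* counts match the aggregate
table exactly: every record carries its true region, and node-field
memberships are assigned within each region so that every column count is
reproduced and every record drains to at least one field.  All single-field
statistics (drainage probabilities, tumour prevalence, per-field prevalence)
depend only on these marginals and are therefore exact; joint multi-field
drainage statistics are NOT recoverable from this reconstruction and must not
be read off it.
"""

from __future__ import annotations

import numpy as np

from .cohort import (
    N_REGIONS,
    NODE_FIELDS,
    Cohort,
    ContingencyTable,
    TumourRecord,
)

__all__ = ["reference_contingency", "reconstruct_reference_cohort"]

#: Tumours per clockface region 0..12, reflected to the left side (N = 869).
REGION_TOTALS = (111, 85, 199, 94, 56, 41, 31, 24, 23, 23, 56, 60, 66)

#: Tumours in each region with >= 1 SLN in each node field (rows sum to the
#: printed per-field totals: 671, 253, 11, 85, 21, 72, 4, 264, 5, 4, 83, 2).
FIELD_COUNTS = {
    "axilla-I-anterior": (87, 66, 164, 69, 44, 31, 20, 21, 19, 19, 42, 41, 48),
    "axilla-I-central": (37, 19, 59, 29, 18, 11, 10, 5, 7, 6, 16, 14, 22),
    "axilla-I-lateral": (1, 3, 2, 1, 0, 0, 1, 0, 0, 0, 1, 1, 1),
    "axilla-I-posterior": (9, 6, 22, 12, 7, 7, 5, 1, 2, 0, 3, 7, 4),
    "axilla-I-interpectoral": (5, 3, 5, 2, 1, 2, 0, 0, 0, 0, 0, 1, 2),
    "axilla-II": (14, 9, 13, 7, 3, 3, 0, 2, 3, 1, 5, 4, 8),
    "axilla-III": (1, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 1),
    "internal-mammary": (37, 19, 28, 14, 16, 16, 16, 17, 15, 11, 28, 29, 18),
    "supraclavicular": (1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0),
    "mediastinal": (1, 0, 0, 0, 0, 0, 1, 0, 0, 1, 0, 1, 0),
    "interval": (13, 4, 16, 11, 4, 10, 5, 4, 1, 1, 3, 6, 5),
    "contralateral": (1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0),
}

_N_BILATERAL = 8  # bilateral patients: 869 tumours from 861 patients
_N_RIGHT = 417  # right-sided tumours before reflection
_SIDE_SEED = 20180412  # fixed: the side split is not published record-level


def reference_contingency() -> ContingencyTable:
    """The aggregate region x node-field counts of the reference cohort."""
    field_counts = np.column_stack([FIELD_COUNTS[f] for f in NODE_FIELDS])
    return ContingencyTable(np.array(REGION_TOTALS), field_counts)


def _assign_fields(region: int) -> list[frozenset[str]]:
    """Deterministic per-region membership assignment matching all marginals.

    The largest-count field fills a prefix of the region's records and the
    second largest a suffix; for every region the two largest counts sum to at
    least the region total, so every record receives >= 1 field.  Remaining
    fields fill prefixes (only marginals are meaningful).
    """
    total = REGION_TOTALS[region]
    counts = sorted(
        ((FIELD_COUNTS[f][region], f) for f in NODE_FIELDS),
        key=lambda cf: (-cf[0], NODE_FIELDS.index(cf[1])),
    )
    member: list[set[str]] = [set() for _ in range(total)]
    (c1, f1), (c2, f2) = counts[0], counts[1]
    assert c1 + c2 >= total, f"region {region}: top-2 counts do not cover the region"
    for i in range(c1):
        member[i].add(f1)
    for i in range(total - c2, total):
        member[i].add(f2)
    for c, f in counts[2:]:
        for i in range(c):
            member[i].add(f)
    return [frozenset(m) for m in member]


def reconstruct_reference_cohort(reflected: bool = True) -> Cohort:
    """Build the deterministic 869-record reconstruction.

    Parameters
    ----------
    reflected
        If True (default) all records are left-sided, as in the aggregate
        table.  If False, 417 deterministically chosen records are restored
        to the right side with mirrored clockface, so that running the
        preprocessing pipeline (reclassify + reflect) reproduces the
        aggregate table exactly.
    """
    n_total = sum(REGION_TOTALS)
    regions = np.repeat(np.arange(N_REGIONS), REGION_TOTALS)
    memberships: list[frozenset[str]] = []
    for r in range(N_REGIONS):
        memberships.extend(_assign_fields(r))

    # Bilateral pairing and side split are unpublished at record level; both
    # are fixed deterministically (see module docstring).
    patient_of: np.ndarray = np.empty(n_total, dtype=int)
    for i in range(_N_BILATERAL):
        patient_of[i] = i
        patient_of[n_total - 1 - i] = i
    singles = np.arange(_N_BILATERAL, n_total - _N_BILATERAL)
    patient_of[singles] = np.arange(len(singles)) + _N_BILATERAL

    rng = np.random.default_rng(_SIDE_SEED)
    right = np.zeros(n_total, dtype=bool)
    # bilateral pairs sit on opposite sides (prefix record L, suffix record R);
    # the remaining right-sided records are drawn from the singletons only
    right[n_total - _N_BILATERAL:] = True
    right[singles[rng.choice(len(singles), size=_N_RIGHT - _N_BILATERAL, replace=False)]] = True

    ages = np.round(np.clip(rng.normal(60.0, 11.0, size=n_total), 25.5, 92.5), 1)
    male_records = set(rng.choice(singles, size=5, replace=False).tolist())

    records = []
    for i in range(n_total):
        r = int(regions[i])
        clock = r
        side = "L"
        if not reflected and right[i]:
            side = "R"
            clock = r if r in (0, 12) else 12 - r
        records.append(
            TumourRecord(
                patient_id=f"P{patient_of[i]:04d}",
                sex="M" if i in male_records else "F",
                age_years=float(ages[i]),
                side=side,
                clockface=clock,
                nipple_distance_cm=0.5 if r == 0 else 2.0 + 0.5 * r,
                drained_fields=memberships[i],
            )
        )
    return Cohort(tuple(records))
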