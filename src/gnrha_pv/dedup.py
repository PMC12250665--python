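"""Duplicate-report removal.

Two reports are duplicates when case ID, report date, and the patient
characteristics (age, sex, country) all coincide. The first-encountered
report of each duplicate group is kept; missing values compare equal to
missing, so two reports that are both silent on age still collapse.
"""

from __future__ import annotations

from typing import Sequence

from gnrha_pv.types import CaseReport

DEFAULT_KEYS = ("case_id", "receipt_date", "age_years", "sex", "country")


def deduplicate(
    reports: Sequence[CaseReport],
    keys: Sequence[str] = DEFAULT_KEYS,
    keep_latest_version: bool = False,
) -> tuple[list[CaseReport], int]:
    """Remove duplicate reports, preserving input order of the kept ones.

    Parameters
    ----------
    reports
        Corpus to deduplicate.
    keys
        CaseReport attribute names that must all be equal for two reports
        to count as duplicates.
    keep_latest_version
        When True, additionally collapse same-``case_id`` reports that
        differ elsewhere, keeping the one with the latest ``receipt_date``
        (FAERS follow-up versions). Off by default.

    Returns
    -------
    (kept, removed_count) with ``len(kept) + removed_count == len(reports)``.
    """
    seen: set[tuple] = set()
    kept: list[CaseReport] = []
    for r in reports:
        sig = tuple(getattr(r, k) for k in keys)
        if sig in seen:
            continue
        seen.add(sig)
        kept.append(r)

    if keep_latest_version:
        latest: dict[str, CaseReport] = {}
        for r in kept:
            cur = latest.get(r.case_id)
            if cur is None:
                latest[r.case_id] = r
            else:
                # None dates sort earliest; ties keep the first seen
                cur_d, new_d = cur.receipt_date, r.receipt_date
                if cur_d is None or (new_d is not None and new_d > cur_d):
                    latest[r.case_id] = r
        chosen = set(map(id, latest.values()))
        kept = [r for r in kept if id(r) in chosen]

    return kept, len(reports) - len(kept)
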