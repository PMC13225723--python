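"""Brute-force reference for the billing engine.

Independent of the engine's branching: enumerates every candidate multiset
of code instances, keeps the ones that are feasible under the time/frequency
constraints via sequential fill (base filled to its maximum before an add-on
starts, each instance reaching its minimum), and selects by maximizing
billable minutes with ties broken by code precedence (CoCM base before
management before General BHI). Reasons follow the precedence: service
requirements, then scenario availability, then time thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class _Spec:
    code: str
    kind: str  # "range" | "set"
    lo: int
    hi: int


def _specs(initial_billed: bool):
    base = _Spec("99492", "range", 36, 70) if not initial_billed else _Spec("99493", "range", 31, 60)
    addon = _Spec("99494", "range", 16, 30)
    return {
        "base": base,
        "addon": addon,
        "G2214": _Spec("G2214", "range", 16, 30),
        "99484": _Spec("99484", "set", 20, 20),
        "G0511": _Spec("G0511", "set", 20, 20),
        "G0512": _Spec("G0512", "set", 70 if not initial_billed else 60, 70 if not initial_billed else 60),
    }


def _allocate(combo: list[_Spec], total: int):
    """Sequential fill; returns credited list or None if infeasible."""
    remaining = total
    credits = []
    for spec in combo:
        if remaining < spec.lo:
            return None
        credit = spec.hi if spec.kind == "set" else min(remaining, spec.hi)
        credits.append(credit)
        remaining -= credit
    return credits


def oracle_assign(
    total: int,
    has_cm: bool,
    has_bhc: bool,
    has_mbc: bool,
    is_fqhc: bool,
    initial_billed: bool,
    availability: dict[str, bool],
):
    """Reference decision: (line items, billable, reasons dict, billed_initial)."""
    cocm_met = has_cm and has_bhc and has_mbc
    bhi_met = has_cm and has_mbc

    if not cocm_met and not bhi_met:
        return [], 0, ({"MISSING_SERVICES": total} if total else {}), False

    specs = _specs(initial_billed)
    if is_fqhc:
        combos = ([[specs["G0512"]]] if cocm_met else []) + [[specs["G0511"]]]
        rank = {"G0512": 0, "G0511": 1}
    elif cocm_met:
        combos = [
            [specs["base"], specs["addon"], specs["addon"]],
            [specs["base"], specs["addon"]],
            [specs["base"]],
            [specs["G2214"]],
            [specs["99484"]],
        ]
        rank = {specs["base"].code: 0, "G2214": 1, "99484": 2}
    else:
        combos = [[specs["99484"]]]
        rank = {"99484": 0}

    feasible = []
    for combo in combos:
        credits = _allocate(combo, total)
        if credits is not None:
            feasible.append((combo, credits))

    available_feasible = [
        (combo, credits)
        for combo, credits in feasible
        if all(availability.get(s.code, False) for s in combo)
    ]

    if not available_feasible:
        if feasible:  # only excluded codes could have billed this month
            return [], 0, {"CODE_UNAVAILABLE_RESTRICTIVE": total}, False
        return [], 0, ({"UNDER_MINIMUM": total} if total else {}), False

    def key(cc):
        combo, credits = cc
        return (-sum(credits), rank[combo[0].code])

    combo, credits = min(available_feasible, key=key)
    billable = sum(credits)
    reasons = {"OVER_MAXIMUM": total - billable} if total > billable else {}
    items = [(s.code, c) for s, c in zip(combo, credits)]
    billed_initial = any(
        code == ("G0512" if is_fqhc else "99492") for code, _ in items
    )
    return items, billable, reasons, billed_initial
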