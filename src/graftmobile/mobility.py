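"""Movement-direction and chilling-response classification of mobile mRNAs.

Direction is defined relative to the transcript's species of origin, per
condition, aggregating over destination tissues: a transcript found only on
the far side of grafts where its species is the scion moved scion to
rootstock; only where its species is the rootstock, rootstock to scion;
both, bidirectional.  Comparing the control and chilling direction calls
yields four mutually exclusive response categories.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

SCION_TO_ROOTSTOCK = "scion_to_rootstock"
ROOTSTOCK_TO_SCION = "rootstock_to_scion"
BIDIRECTIONAL = "bidirectional"
DIRECTIONS = (SCION_TO_ROOTSTOCK, ROOTSTOCK_TO_SCION, BIDIRECTIONAL)

CHILLING_INDUCED = "chilling_induced"
CHILLING_REDUCED = "chilling_reduced"
DIRECTION_CHANGED = "direction_changed"
DIRECTION_MAINTAINED = "direction_maintained"
CATEGORIES = (CHILLING_INDUCED, CHILLING_REDUCED, DIRECTION_CHANGED, DIRECTION_MAINTAINED)


def _movement_role(origin_species: str, graft: str, tissue: str) -> str:
    scion, rootstock = graft.split("/")
    resident = scion if tissue == "leaf" else rootstock
    if resident == origin_species:
        raise ValueError(
            f"corrupt mobility call: destination {graft} {tissue} is resident "
            f"tissue of origin species {origin_species}"
        )
    if origin_species == scion:
        return SCION_TO_ROOTSTOCK
    if origin_species == rootstock:
        return ROOTSTOCK_TO_SCION
    raise ValueError(f"origin species {origin_species} absent from graft {graft}")


def assign_direction(calls: pd.DataFrame, species: str, condition: str) -> pd.DataFrame:
    """One direction record per transcript of ``species`` mobile under ``condition``.

    ``calls`` is the mobility table (one row per transcript x destination);
    only rows with ``is_mobile`` are considered.
    """
    sub = calls[
        (calls["origin"] == species)
        & (calls["condition"] == condition)
        & (calls["is_mobile"])
    ]
    rows = []
    for tid, grp in sub.groupby("transcript"):
        roles = {
            _movement_role(species, row.graft, row.tissue)
            for row in grp.itertuples(index=False)
        }
        if roles == {SCION_TO_ROOTSTOCK}:
            direction = SCION_TO_ROOTSTOCK
        elif roles == {ROOTSTOCK_TO_SCION}:
            direction = ROOTSTOCK_TO_SCION
        else:
            direction = BIDIRECTIONAL
        rows.append(
            {"transcript": tid, "species": species, "condition": condition, "direction": direction}
        )
    return pd.DataFrame(rows, columns=["transcript", "species", "condition", "direction"]).sort_values(
        "transcript", ignore_index=True
    )


def classify_condition_response(
    directions_control: pd.DataFrame, directions_chilling: pd.DataFrame
) -> pd.DataFrame:
    """Four-way chilling-response category per transcript mobile in >= 1 condition.

    chilling only -> chilling_induced; control only -> chilling_reduced;
    both conditions with a different direction -> direction_changed; both
    with the same direction -> direction_maintained.
    """
    ctrl = directions_control.set_index("transcript")
    chill = directions_chilling.set_index("transcript")
    rows = []
    for tid in sorted(set(ctrl.index) | set(chill.index)):
        in_ctrl, in_chill = tid in ctrl.index, tid in chill.index
        if in_chill and not in_ctrl:
            category, species = CHILLING_INDUCED, chill.loc[tid, "species"]
        elif in_ctrl and not in_chill:
            category, species = CHILLING_REDUCED, ctrl.loc[tid, "species"]
        elif ctrl.loc[tid, "direction"] != chill.loc[tid, "direction"]:
            category, species = DIRECTION_CHANGED, chill.loc[tid, "species"]
        else:
            category, species = DIRECTION_MAINTAINED, chill.loc[tid, "species"]
        rows.append({"transcript": tid, "species": species, "category": category})
    return pd.DataFrame(rows, columns=["transcript", "species", "category"])


def percent(count: int, total: int) -> float:
    """100 * count / total, rounded half-up to one decimal place."""
    if total < 1:
        raise ValueError("total must be >= 1")
    value = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(value)


def summarize_direction_counts(
    counts: dict[str, int], total: int | None = None
) -> pd.DataFrame:
    """Percentage summary from per-direction counts.

    ``total`` defaults to the sum of the counts; it may be given explicitly
    when the counts are a subset of a larger classified universe.
    """
    if total is None:
        total = sum(counts.values())
    if total < 1:
        raise ValueError("cannot summarize an empty direction table")
    rows = [
        {"direction": d, "count": n, "percent": percent(n, total)}
        for d, n in counts.items()
    ]
    frame = pd.DataFrame(rows, columns=["direction", "count", "percent"])
    frame["total"] = total
    return frame


def summarize_directions(directions: pd.DataFrame) -> pd.DataFrame:
    """Count each direction class and express it as a 1-decimal percentage."""
    if directions.empty:
        raise ValueError("cannot summarize an empty direction table")
    counts = {
        d: int((directions["direction"] == d).sum())
        for d in DIRECTIONS
        if (directions["direction"] == d).any()
    }
    return summarize_direction_counts(counts)
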