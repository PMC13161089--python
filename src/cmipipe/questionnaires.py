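"""Post-concussion and dizziness questionnaire scoring.

Two instruments are supported:

* RPQ — a 16-item post-concussion symptom questionnaire on a 0-4 ordinal
  scale.  The first three items (headaches, dizziness, nausea) sum to the
  early physical cluster (RPQ-3, max 12); the remaining thirteen sum to
  the later psychological/cognitive cluster (RPQ-13, max 52).  A rating
  of 1 means "no more a problem": it is kept in the sums but does not
  count as an endorsed symptom — endorsement requires a rating of 2 or
  greater.
* DHI — a 25-item dizziness handicap inventory whose physical,
  functional and emotional domain scores sum to a 100-point total.  Item
  point values and the item -> domain map are configurable "schemes":
  the default ``paper`` scheme has domain maxima 24/40/36 (6 physical,
  10 functional, 9 emotional items at 4 points each); the ``standard``
  scheme follows the published instrument with 28/36/36 (7/9/9 items).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RPQ_ITEMS",
    "RPQScores",
    "DHIScores",
    "DHIScheme",
    "DHI_SCHEMES",
    "score_rpq",
    "score_dhi",
    "score_questionnaire_table",
    "summarize_cohort",
]

# Item order fixes the 3/13 split: the first three are the early physical
# symptoms, the remaining thirteen the later psychological/cognitive ones.
RPQ_ITEMS = [
    "headaches",
    "dizziness",
    "nausea",
    "noise_sensitivity",
    "sleep_disturbance",
    "fatigue",
    "irritability",
    "depression",
    "frustration",
    "forgetfulness",
    "poor_concentration",
    "taking_longer_to_think",
    "blurred_vision",
    "light_sensitivity",
    "double_vision",
    "restlessness",
]

ENDORSEMENT_THRESHOLD = 2  # rating >= 2 counts as an endorsed symptom


@dataclass
class RPQScores:
    rpq3: int
    rpq13: int
    endorsement: dict[str, bool]

    @property
    def total(self) -> int:
        return self.rpq3 + self.rpq13


@dataclass
class DHIScores:
    physical: int
    functional: int
    emotional: int

    @property
    def total(self) -> int:
        return self.physical + self.functional + self.emotional


@dataclass(frozen=True)
class DHIScheme:
    """Item -> domain map with per-item maximum points."""

    name: str
    items: tuple  # ((item_name, domain), ...) in instrument order
    item_max: int = 4  # each item scored 0 / 2 / 4

    @property
    def domain_maxima(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, dom in self.items:
            out[dom] = out.get(dom, 0) + self.item_max
        return out

    @property
    def total_max(self) -> int:
        return sum(self.domain_maxima.values())


def _mk_items(counts: dict[str, int]) -> tuple:
    return tuple(
        (f"{dom[0]}{i + 1}", dom) for dom, k in counts.items() for i in range(k)
    )


DHI_SCHEMES = {
    # domain maxima 24 / 40 / 36 (physical / functional / emotional)
    "paper": DHIScheme(
        "paper", _mk_items({"physical": 6, "functional": 10, "emotional": 9})
    ),
    # published instrument: 28 / 36 / 36
    "standard": DHIScheme(
        "standard", _mk_items({"physical": 7, "functional": 9, "emotional": 9})
    ),
}


def score_rpq(ratings: list[int] | np.ndarray | dict[str, int]) -> RPQScores:
    """Score one 16-item RPQ response.

    Accepts ratings in instrument order, or a mapping from item name to
    rating.  Ratings of 1 are included in the sums but never endorsed.
    """
    if isinstance(ratings, dict):
        missing = [i for i in RPQ_ITEMS if i not in ratings]
        if missing:
            raise ValueError(f"missing RPQ items: {missing}")
        vals = np.array([ratings[i] for i in RPQ_ITEMS])
    else:
        vals = np.asarray(ratings)
    if vals.shape != (16,):
        raise ValueError(f"RPQ needs exactly 16 items, got {vals.shape}")
    if not np.issubdtype(vals.dtype, np.integer):
        if not np.allclose(vals, np.rint(vals)):
            raise ValueError("RPQ ratings must be integers")
        vals = np.rint(vals).astype(int)
    if vals.min() < 0 or vals.max() > 4:
        raise ValueError("RPQ ratings must lie in 0-4")
    return RPQScores(
        rpq3=int(vals[:3].sum()),
        rpq13=int(vals[3:].sum()),
        endorsement={
            item: bool(v >= ENDORSEMENT_THRESHOLD)
            for item, v in zip(RPQ_ITEMS, vals)
        },
    )


def score_dhi(
    ratings: list[int] | np.ndarray | dict[str, int],
    scheme: str | DHIScheme = "paper",
) -> DHIScores:
    """Score one 25-item DHI response under a scoring scheme."""
    if isinstance(scheme, str):
        scheme = DHI_SCHEMES[scheme]
    if scheme.total_max != 100:
        import warnings

        warnings.warn(
            f"scheme {scheme.name!r} domain maxima sum to {scheme.total_max}, not 100",
            stacklevel=2,
        )
    names = [n for n, _ in scheme.items]
    if isinstance(ratings, dict):
        missing = [n for n in names if n not in ratings]
        if missing:
            raise ValueError(f"missing DHI items: {missing}")
        vals = np.array([ratings[n] for n in names])
    else:
        vals = np.asarray(ratings)
    if vals.shape != (len(names),):
        raise ValueError(f"DHI needs exactly {len(names)} items, got {vals.shape}")
    if vals.min() < 0 or vals.max() > scheme.item_max:
        raise ValueError(f"DHI ratings must lie in 0-{scheme.item_max}")
    sums = {"physical": 0, "functional": 0, "emotional": 0}
    for (name, dom), v in zip(scheme.items, vals):
        sums[dom] += int(v)
    return DHIScores(**sums)


def score_questionnaire_table(
    items: pd.DataFrame, scheme: str | DHIScheme = "paper"
) -> pd.DataFrame:
    """Score a long-format item table into per-participant severity scores.

    Expects columns participant, instrument (RPQ/DHI), item_index, rating
    (the layout the synthetic generator writes).  Returns one row per
    participant with rpq3, rpq13, dhi_physical, dhi_functional,
    dhi_emotional, dhi_total.
    """
    rows = []
    for pid, grp in items.groupby("participant"):
        row: dict = {"participant": pid}
        rpq = grp[grp["instrument"] == "RPQ"].sort_values("item_index")
        if len(rpq):
            rs = score_rpq(rpq["rating"].to_numpy())
            row |= {"rpq3": rs.rpq3, "rpq13": rs.rpq13, "rpq_total": rs.total}
        dhi = grp[grp["instrument"] == "DHI"].sort_values("item_index")
        if len(dhi):
            ds = score_dhi(dhi["rating"].to_numpy(), scheme)
            row |= {
                "dhi_physical": ds.physical,
                "dhi_functional": ds.functional,
                "dhi_emotional": ds.emotional,
                "dhi_total": ds.total,
            }
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_cohort(
    items: pd.DataFrame, instrument: str = "RPQ"
) -> pd.DataFrame:
    """Endorsement frequency table: per item, the number and percentage of
    participants rating it >= 2, and the mean +/- SD rating among
    endorsers.

    Percentages carry two decimals (e.g. 19 of 22 -> 86.36).
    """
    sub = items[items["instrument"] == instrument]
    if sub.empty:
        raise ValueError(f"no rows for instrument {instrument!r}")
    n = sub["participant"].nunique()
    rows = []
    for (idx, item), grp in sub.groupby(["item_index", "item"]):
        endorsed = grp[grp["rating"] >= ENDORSEMENT_THRESHOLD]["rating"]
        k = len(endorsed)
        rows.append(
            {
                "item_index": idx,
                "item": item,
                "n_endorsed": k,
                "pct_endorsed": round(100.0 * k / n, 2),
                "mean_rating_endorsers": (
                    round(float(endorsed.mean()), 2) if k else np.nan
                ),
                "sd_rating_endorsers": (
                    round(float(endorsed.std(ddof=1)), 2) if k > 1 else np.nan
                ),
            }
        )
    return pd.DataFrame(rows).sort_values("item_index").reset_index(drop=True)
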