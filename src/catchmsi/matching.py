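"""Frequency matching of MSS controls to MSI cases.

Controls are drawn so the joint composition over (lineage group, APC flag,
TP53 flag) matches the cases at a fixed ratio — frequency matching, not
1:1 pair matching. When a stratum's control pool is short, the matching key
is relaxed one component at a time in the fixed order
lineage -> TP53 -> APC, and every relaxed draw is logged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .synthetic import MUTATION_STATES

__all__ = ["StratumKey", "MatchResult", "MatchingError",
           "DEFAULT_LINEAGE_MAP", "assign_strata", "frequency_match"]


class MatchingError(ValueError):
    pass


class StratumKey(NamedTuple):
    lineage: str
    apc: str
    tp53: str


#: Raw lineage string -> one of the five lineage groups. User-editable:
#: pass your own mapping (or a CSV via the CLI) for cohorts with other
#: lineage vocabularies. Keys are matched case-insensitively.
DEFAULT_LINEAGE_MAP = {
    # the five groups map to themselves
    "gi": "GI", "breast/gyn": "Breast/GYN", "hema": "Hema", "gu": "GU",
    "other": "other",
    # gastrointestinal
    "colorectal": "GI", "bowel": "GI", "colon": "GI", "rectum": "GI",
    "gastric": "GI", "stomach": "GI", "esophagus": "GI", "pancreas": "GI",
    "liver": "GI", "bile_duct": "GI", "biliary_tract": "GI",
    # breast and gynecologic
    "breast": "Breast/GYN", "ovary": "Breast/GYN", "ovarian": "Breast/GYN",
    "uterus": "Breast/GYN", "endometrium": "Breast/GYN",
    "cervix": "Breast/GYN", "cervical": "Breast/GYN",
    # hematologic
    "leukemia": "Hema", "lymphoma": "Hema", "myeloma": "Hema",
    "blood": "Hema", "lymphocyte": "Hema", "plasma_cell": "Hema",
    # genitourinary
    "bladder": "GU", "kidney": "GU", "prostate": "GU",
    "urinary_tract": "GU", "testis": "GU",
    # everything else commonly seen
    "lung": "other", "skin": "other", "brain": "other", "cns": "other",
    "bone": "other", "soft_tissue": "other", "thyroid": "other",
    "head_and_neck": "other", "peripheral_nervous_system": "other",
    "eye": "other", "adrenal": "other", "pleura": "other",
}


@dataclass
class MatchResult:
    case_ids: list
    control_ids: list
    stratum_table: pd.DataFrame
    relaxation_log: list = field(default_factory=list)
    seed: int = 0


def assign_strata(annotation: pd.DataFrame, lineage_map=None) -> list:
    """Per-sample StratumKey list from annotation columns.

    Raw lineage strings are collapsed into the five groups via the mapping
    table; unknown strings (or missing values) are input errors.
    """
    for col in ("lineage", "apc", "tp53"):
        if col not in annotation.columns:
            raise MatchingError(f"annotation is missing column {col!r}")
    mapping = {k.lower(): v for k, v in (lineage_map or DEFAULT_LINEAGE_MAP).items()}

    raw = annotation["lineage"]
    if raw.isna().any():
        raise MatchingError("missing lineage annotation is an input error")
    unknown = sorted({str(v) for v in raw if str(v).strip().lower() not in mapping})
    if unknown:
        raise MatchingError(
            f"unmapped lineage value(s): {unknown}; extend the lineage map"
        )
    groups = [mapping[str(v).strip().lower()] for v in raw]

    keys = []
    for sid, grp, apc, tp53 in zip(annotation.index, groups,
                                   annotation["apc"], annotation["tp53"]):
        if apc not in MUTATION_STATES or tp53 not in MUTATION_STATES:
            raise MatchingError(
                f"sample {sid!r}: apc/tp53 flags must be 'M' or 'W', "
                f"got ({apc!r}, {tp53!r})"
            )
        keys.append(StratumKey(grp, str(apc), str(tp53)))
    return keys


# relaxation cascade: which key components are compared at each level
_RELAX_LEVELS = (
    ("lineage", "apc", "tp53"),   # exact joint stratum
    ("apc", "tp53"),              # drop lineage
    ("apc",),                     # drop TP53 too
    (),                           # drop APC: anyone
)


def _project(key: StratumKey, fields) -> tuple:
    return tuple(getattr(key, f) for f in fields)


def frequency_match(cases: pd.DataFrame, control_pool: pd.DataFrame,
                    ratio: int = 3, seed: int = 0,
                    lineage_map=None) -> MatchResult:
    """Draw ``ratio`` controls per case, frequency-matched on the joint
    (lineage, APC, TP53) stratum.

    Per stratum with c cases, ``ratio * c`` controls are drawn uniformly
    without replacement from that stratum of the pool; shortfalls backfill
    through the relaxation cascade (lineage dropped first, then TP53, then
    APC), each relaxed draw logged. Deterministic given ``seed``.
    """
    if ratio < 1:
        raise MatchingError("ratio must be a positive integer")
    overlap = cases.index.intersection(control_pool.index)
    if len(overlap):
        raise MatchingError(f"case and control pools overlap: {overlap[:5].tolist()}")

    case_keys = assign_strata(cases, lineage_map)
    pool_keys = assign_strata(control_pool, lineage_map)
    pool_ids = list(control_pool.index)

    demand = Counter(case_keys)
    need = {k: ratio * c for k, c in demand.items()}
    total_need = sum(need.values())
    if total_need > len(pool_ids):
        raise MatchingError(
            f"control pool ({len(pool_ids)}) smaller than ratio x cases "
            f"({total_need}); shortfall {total_need - len(pool_ids)}"
        )

    rng = np.random.default_rng(seed)
    available = dict.fromkeys(pool_ids, True)
    key_of = dict(zip(pool_ids, pool_keys))
    selected: dict = {}          # stratum -> list of control ids
    relaxation_log: list = []

    for level, fields in enumerate(_RELAX_LEVELS):
        for stratum in sorted(need):
            remaining = need[stratum] - len(selected.get(stratum, []))
            if remaining <= 0:
                continue
            target = _project(stratum, fields)
            candidates = [pid for pid in pool_ids
                          if available[pid] and _project(key_of[pid], fields) == target]
            take = min(remaining, len(candidates))
            if take == 0:
                continue
            drawn = list(rng.choice(candidates, size=take, replace=False))
            for pid in drawn:
                available[pid] = False
            selected.setdefault(stratum, []).extend(drawn)
            if level > 0:
                relaxation_log.append(
                    {"stratum": stratum, "level": level,
                     "relaxed_to": fields, "n_drawn": take}
                )

    shortfall = {k: v - len(selected.get(k, [])) for k, v in need.items()
                 if v > len(selected.get(k, []))}
    if shortfall:
        raise MatchingError(
            f"pool exhausted even after full relaxation; shortfall {shortfall}"
        )

    control_ids = [pid for k in sorted(selected) for pid in selected[k]]
    rows = []
    ctrl_strata = Counter(key_of[pid] for pid in control_ids)
    for stratum in sorted(set(demand) | set(ctrl_strata)):
        rows.append({
            "lineage": stratum.lineage, "apc": stratum.apc,
            "tp53": stratum.tp53,
            "n_cases": demand.get(stratum, 0),
            "n_controls": ctrl_strata.get(stratum, 0),
        })
    table = pd.DataFrame(rows)
    return MatchResult(case_ids=list(cases.index), control_ids=control_ids,
                       stratum_table=table, relaxation_log=relaxation_log,
                       seed=seed)
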