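"""Trial-level data model, tidy CSV I/O and participant-exclusion bookkeeping.

One trial of the size-discrimination grasping task pairs a dichotomous
perceptual judgement (is the front object larger or smaller than the back
object?) with a continuous visuomotor measure (the maximum grip aperture,
MGA, of the grasp directed at the front object). The two objects differ by
0.5 mm (40.0 vs 40.5 mm), which is below the just-noticeable difference for
most observers, so both correct and incorrect judgements occur in every
session.

The within-subject ANOVA conditions trials on judgement correctness, so a
participant who never produced, say, an incorrect "larger" response for the
small object in one block has an empty design cell and cannot enter the
ANOVA. The optimal cut-off (OC%) analysis only needs MGAs per object size
and keeps such participants. :class:`ParticipantSet` records both
eligibility sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

EXPERIMENTS = ("E1", "E2", "E3")
VISIONS = ("closed_loop", "open_loop", "none")
RESPONSES = ("larger", "smaller")

#: canonical column order of the tidy trial table
COLUMNS = (
    "participant_id",
    "experiment",
    "block",
    "vision",
    "target_size_mm",
    "distractor_size_mm",
    "verbal_response",
    "verbal_correct",
    "mga_mm",
    "valid",
    "invalid_reason",
)

MISSING = "NA"  #: sentinel written for a missing MGA


@dataclass
class TrialRecord:
    """One grasping + judgement trial.

    ``target_size_mm`` is the front (grasped) object, ``distractor_size_mm``
    the back object; ``verbal_response`` states the front object's size
    relative to the back one. ``verbal_correct`` is always derivable from
    sizes and response. ``mga_mm`` is ``None`` when the kinematic record was
    unusable; such trials still count for verbal accuracy. ``valid=False``
    marks structurally broken rows, which no analysis uses.
    """

    participant_id: str
    experiment: str
    block: int
    vision: str
    target_size_mm: float
    distractor_size_mm: float
    verbal_response: str
    verbal_correct: bool = field(default=False)
    mga_mm: float | None = None
    valid: bool = True
    invalid_reason: str = ""

    def __post_init__(self) -> None:
        self.verbal_correct = derive_verbal_correct(
            self.verbal_response, self.target_size_mm, self.distractor_size_mm
        )


def derive_verbal_correct(
    response: str, target_size_mm: float, distractor_size_mm: float
) -> bool:
    """A response is correct iff it names the true relative size of the front object."""
    if response not in RESPONSES:
        raise ValueError(f"verbal_response must be one of {RESPONSES}, got {response!r}")
    return (response == "larger") == (target_size_mm > distractor_size_mm)


@dataclass
class ParticipantSet:
    """Trials of one experiment plus the two eligibility sets.

    ``anova_eligible`` holds participants with at least one valid MGA trial
    in every design cell (size x judgement-correctness x block, or x vision
    for the closed/open-loop experiment); ``occ_eligible`` holds everyone
    for whom an optimal cut-off can be computed and is always a superset.
    """

    records: list[TrialRecord]
    anova_eligible: set[str]
    occ_eligible: set[str]

    @property
    def participants(self) -> list[str]:
        """Participant ids ordered by first appearance (deterministic output order)."""
        return _ordered_participants(self.records)


def _ordered_participants(records: Iterable[TrialRecord]) -> list[str]:
    seen: dict[str, None] = {}
    for r in records:
        seen.setdefault(r.participant_id, None)
    return list(seen)


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tidy long table with one row per trial, canonical column order."""
    rows = [
        {
            "participant_id": r.participant_id,
            "experiment": r.experiment,
            "block": r.block,
            "vision": r.vision,
            "target_size_mm": r.target_size_mm,
            "distractor_size_mm": r.distractor_size_mm,
            "verbal_response": r.verbal_response,
            "verbal_correct": r.verbal_correct,
            "mga_mm": r.mga_mm,
            "valid": r.valid,
            "invalid_reason": r.invalid_reason,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(COLUMNS))


def load_column_mapping(path: str | Path) -> dict[str, str]:
    """Read a YAML (or flat ``key=value``) file mapping foreign column names to canonical ones."""
    text = Path(path).read_text()
    try:
        mapping = yaml.safe_load(text)
    except yaml.YAMLError:
        mapping = None
    if not isinstance(mapping, dict):
        mapping = {}
        for line in text.splitlines():
            line = line.strip()
            if line and not line.startswith("#") and "=" in line:
                k, v = line.split("=", 1)
                mapping[k.strip()] = v.strip()
    return {str(k): str(v) for k, v in mapping.items()}


def read_trials(
    path: str | Path, mapping: Mapping[str, str] | None = None
) -> list[TrialRecord]:
    """Read a delimited trial table into validated :class:`TrialRecord` objects.

    Parameters
    ----------
    path
        CSV file (UTF-8, ``.`` decimal separator) with a header row.
    mapping
        Optional ``{file column -> canonical column}`` remapping for foreign
        files whose headers differ from :data:`COLUMNS`.

    Rows failing validation are flagged ``valid=False`` with a reason and
    kept, never silently dropped; a missing mandatory column is a hard
    error, as is a ``verbal_correct`` column that contradicts the sizes and
    response (the derived value is authoritative, a contradiction means the
    file is corrupt).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if mapping:
        df = df.rename(columns=dict(mapping))
    mandatory = [
        "participant_id",
        "experiment",
        "block",
        "vision",
        "target_size_mm",
        "distractor_size_mm",
        "verbal_response",
        "mga_mm",
    ]
    for col in mandatory:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col!r}")

    records: list[TrialRecord] = []
    contradictions: list[int] = []
    for i, row in df.iterrows():
        valid = True
        reason = ""
        try:
            block = int(row["block"])
            target = float(row["target_size_mm"])
            distractor = float(row["distractor_size_mm"])
        except ValueError as exc:
            # unparseable numerics invalidate the row, not the file
            logger.warning("row %d invalid: %s", i, exc)
            records.append(
                TrialRecord(
                    participant_id=str(row["participant_id"]),
                    experiment=str(row["experiment"]),
                    block=0,
                    vision=str(row["vision"]),
                    target_size_mm=40.0,
                    distractor_size_mm=40.5,
                    verbal_response="larger",
                    valid=False,
                    invalid_reason=str(exc),
                )
            )
            continue
        response = str(row["verbal_response"])
        if response not in RESPONSES:
            valid, reason = False, f"bad verbal_response {response!r}"
            response = "larger"
        if str(row["experiment"]) not in EXPERIMENTS:
            valid, reason = False, f"bad experiment {row['experiment']!r}"
        if str(row["vision"]) not in VISIONS:
            valid, reason = False, f"bad vision {row['vision']!r}"
        if target == distractor:
            valid, reason = False, "target and distractor sizes equal"

        raw_mga = str(row["mga_mm"]).strip()
        mga: float | None
        if raw_mga in ("", MISSING, "nan", "NaN"):
            mga = None
            logger.info("row %d: missing MGA", i)
        else:
            try:
                mga = float(raw_mga)
                if not mga > 0:
                    valid, reason = False, f"non-positive mga_mm {mga}"
                    mga = None
            except ValueError:
                valid, reason = False, f"unparseable mga_mm {raw_mga!r}"
                mga = None

        rec = TrialRecord(
            participant_id=str(row["participant_id"]),
            experiment=str(row["experiment"]),
            block=block,
            vision=str(row["vision"]),
            target_size_mm=target,
            distractor_size_mm=distractor,
            verbal_response=response,
            mga_mm=mga,
            valid=valid,
            invalid_reason=reason,
        )
        if valid and "verbal_correct" in df.columns:
            stated = str(row["verbal_correct"]).strip().lower()
            if stated in ("true", "false") and (stated == "true") != rec.verbal_correct:
                contradictions.append(int(i))
        records.append(rec)

    if contradictions:
        raise ValueError(
            "verbal_correct column contradicts sizes and response at rows "
            f"{contradictions}"
        )
    return records


def write_trials(records: Sequence[TrialRecord], path: str | Path) -> None:
    """Write records as a tidy CSV; missing MGA serialises as the ``NA`` sentinel.

    Round-trips exactly: ``read_trials(write_trials(x)) == x`` field for field.
    """
    df = records_to_frame(records)
    df["mga_mm"] = df["mga_mm"].map(lambda v: MISSING if pd.isna(v) else repr(float(v)))
    df["verbal_correct"] = df["verbal_correct"].map(lambda b: "True" if b else "False")
    df["valid"] = df["valid"].map(lambda b: "True" if b else "False")
    df.to_csv(path, index=False)


def design_cells(experiment: str, sizes: Sequence[float]) -> list[tuple]:
    """Full crossing of the conditioning factors for one experiment.

    For the single-vision experiments: size x correctness x block 1..3;
    for the closed/open-loop experiment: size x correctness x vision.
    """
    small, big = sorted(sizes)
    if experiment in ("E1", "E2"):
        third: Iterable = (1, 2, 3)
    elif experiment == "E3":
        third = ("closed_loop", "open_loop")
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    return list(product((small, big), (True, False), third))


def _cell_key(rec: TrialRecord) -> tuple:
    third = rec.vision if rec.experiment == "E3" else rec.block
    return (rec.target_size_mm, rec.verbal_correct, third)


def partition_eligibility(records: Sequence[TrialRecord]) -> ParticipantSet:
    """Split participants into ANOVA-eligible and OC%-eligible sets.

    ANOVA eligibility requires >= 1 valid MGA trial in *every* design cell.
    OC% eligibility only requires >= 1 valid MGA per object size within each
    vision condition (the cut-off needs both classes). Participants excluded
    from the ANOVA therefore remain in the OC% analysis.
    """
    recs = [r for r in records if r.valid]
    if not recs:
        raise ValueError("no valid records")
    experiments = {r.experiment for r in recs}
    if len(experiments) != 1:
        raise ValueError(f"records span multiple experiments: {sorted(experiments)}")
    experiment = experiments.pop()
    sizes = sorted({r.target_size_mm for r in recs})
    if len(sizes) != 2:
        raise ValueError(f"expected exactly two target sizes, found {sizes}")

    cells = design_cells(experiment, sizes)
    filled: dict[str, set] = {}
    per_size: dict[str, set] = {}
    for r in recs:
        if r.mga_mm is None:
            continue
        filled.setdefault(r.participant_id, set()).add(_cell_key(r))
        vis = r.vision if experiment == "E3" else "none"
        per_size.setdefault(r.participant_id, set()).add((vis, r.target_size_mm))

    visions = ("closed_loop", "open_loop") if experiment == "E3" else ("none",)
    anova = {p for p, f in filled.items() if all(c in f for c in cells)}
    occ = {
        p
        for p, f in per_size.items()
        if all((v, s) in f for v in visions for s in sizes)
    }
    occ |= anova
    for p in _ordered_participants(recs):
        if p not in anova:
            missing = [c for c in cells if c not in filled.get(p, set())]
            logger.info("participant %s excluded from ANOVA; empty cells: %s", p, missing)
    logger.info(
        "%d participants, %d ANOVA-eligible, %d OC%%-eligible",
        len(_ordered_participants(recs)), len(anova), len(occ),
    )
    return ParticipantSet(records=list(records), anova_eligible=anova, occ_eligible=occ)
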