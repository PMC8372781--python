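"""Domain types and group summary statistics for litter-level teratology data.

The unit of observation is the litter: ``n_i`` live fetuses of which ``a_i``
are affected (malformed). Litters are grouped by dose into a
:class:`LitterStudy`. :func:`summarize_group` computes the per-dose-group
summary statistics used throughout the package:

* ``N_F`` / ``A_F`` — total and affected fetus counts; ``P_F = A_F/N_F`` is
  the ratio estimator of the proportion affected,
* ``N_L`` / ``A_L`` — litter count and count of litters with any affected
  fetus; ``P_L = A_L/N_L``,
* ``P_av`` — unweighted mean of litter proportions ``p_i = a_i/n_i``,
* ``S`` — sample standard deviation (divisor ``N_L − 1``) of the ``p_i``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SchemaError, ValidationError

SPECIES = ("mouse", "rat", "rabbit", "other")

LITTER_COLUMNS = ["study", "species", "dose", "litter", "size", "affected"]

SUMMARY_COLUMNS = [
    "dose",
    "n_litters",
    "n_fetuses",
    "n_affected",
    "p_avg",
    "sd_litter_prop",
    "n_affected_litters",
    "design_effect",
]


@dataclass(frozen=True)
class LitterRecord:
    """One litter: ``size`` live fetuses, ``affected`` of them malformed."""

    study_id: str
    species: str
    dose: float
    litter_id: str
    size: int
    affected: int

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(
                f"litter {self.litter_id!r}: unknown species {self.species!r} "
                f"(expected one of {SPECIES})"
            )
        if self.dose < 0:
            raise ValidationError(
                f"litter {self.litter_id!r}: negative dose {self.dose}"
            )
        if self.size < 1:
            raise ValidationError(
                f"litter {self.litter_id!r}: size must be >= 1, got {self.size}"
            )
        if not 0 <= self.affected <= self.size:
            raise ValidationError(
                f"litter {self.litter_id!r}: affected={self.affected} outside "
                f"[0, size={self.size}]"
            )

    @property
    def proportion(self) -> float:
        """Litter proportion affected, ``p_i = a_i / n_i``."""
        return self.affected / self.size


@dataclass(frozen=True)
class DoseGroup:
    """All litters observed at one dose."""

    dose: float
    litters: tuple[LitterRecord, ...]

    def __post_init__(self) -> None:
        if not self.litters:
            raise ValidationError(f"dose group {self.dose}: no litters")
        for rec in self.litters:
            if rec.dose != self.dose:
                raise ValidationError(
                    f"dose group {self.dose}: litter {rec.litter_id!r} has "
                    f"dose {rec.dose}"
                )

    @property
    def n_litters(self) -> int:
        return len(self.litters)


@dataclass(frozen=True)
class LitterStudy:
    """A developmental-toxicity study: dose groups in ascending dose order."""

    study_id: str
    species: str
    groups: tuple[DoseGroup, ...]

    def __post_init__(self) -> None:
        doses = [g.dose for g in self.groups]
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValidationError(
                f"study {self.study_id!r}: doses must be strictly increasing, "
                f"got {doses}"
            )

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(g.dose for g in self.groups)

    @property
    def control(self) -> DoseGroup | None:
        """The dose-0 group, if present."""
        return self.groups[0] if self.groups and self.groups[0].dose == 0 else None


@dataclass(frozen=True)
class GroupSummary:
    """Per-dose-group summary statistics.

    ``sd_litter_prop`` is NaN when the group has a single litter (the sample
    SD is then undefined). ``n_affected`` is a float so that design-effect
    transformed (fractional) counts can be carried in the same container.
    """

    dose: float
    n_fetuses: int
    n_affected: float
    n_litters: int
    n_affected_litters: int
    p_avg: float
    sd_litter_prop: float

    @property
    def p_fetal(self) -> float:
        return self.n_affected / self.n_fetuses

    @property
    def p_litter(self) -> float:
        return self.n_affected_litters / self.n_litters

    @property
    def mean_litter_size(self) -> float:
        return self.n_fetuses / self.n_litters


def summarize_group(group: DoseGroup) -> GroupSummary:
    """Compute all summary statistics for one dose group."""
    props = np.array([rec.proportion for rec in group.litters])
    n_litters = group.n_litters
    sd = float(np.std(props, ddof=1)) if n_litters >= 2 else math.nan
    return GroupSummary(
        dose=group.dose,
        n_fetuses=sum(rec.size for rec in group.litters),
        n_affected=float(sum(rec.affected for rec in group.litters)),
        n_litters=n_litters,
        n_affected_litters=sum(rec.affected > 0 for rec in group.litters),
        p_avg=float(props.mean()),
        sd_litter_prop=sd,
    )


def summarize_study(study: LitterStudy) -> list[GroupSummary]:
    """Summaries for every dose group, in dose order."""
    return [summarize_group(g) for g in study.groups]


def pooled_litter_sd(
    summaries: Iterable[GroupSummary], weights: str = "df"
) -> float:
    """Pooled standard deviation of litter proportions across dose groups.

    Parameters
    ----------
    weights:
        ``"df"`` (default) pools group variances by degrees of freedom
        ``N_L − 1`` (the standard pooled variance); ``"fetuses"`` weights
        each group variance by its fetus count instead.
    """
    num = 0.0
    den = 0.0
    for s in summaries:
        if s.n_litters < 2 or math.isnan(s.sd_litter_prop):
            continue
        w = (s.n_litters - 1) if weights == "df" else s.n_fetuses
        num += w * s.sd_litter_prop**2
        den += w
    if den == 0:
        raise InsufficientDataError(
            "pooled litter SD undefined: every group has fewer than 2 litters"
        )
    return math.sqrt(num / den)


# ---------------------------------------------------------------------------
# CSV input/output


def _build_study(df: pd.DataFrame, dose_tol: float = 0.0) -> LitterStudy:
    problems: list[str] = []
    records: list[LitterRecord] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            records.append(
                LitterRecord(
                    study_id=str(row["study"]),
                    species=str(row["species"]).strip().lower(),
                    dose=float(row["dose"]),
                    litter_id=str(row["litter"]),
                    size=int(row["size"]),
                    affected=int(row["affected"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise ValidationError(
            "invalid litter rows:\n" + "\n".join(problems)
        )
    if not records:
        raise ValidationError("no litter rows found")

    # group doses, optionally snapping values within dose_tol of each other
    doses: list[float] = []
    for rec in records:
        match = None
        if dose_tol > 0:
            for d in doses:
                if abs(rec.dose - d) <= dose_tol:
                    match = d
                    break
        elif rec.dose in doses:
            match = rec.dose
        if match is None:
            doses.append(rec.dose)
    doses.sort()

    def snap(d: float) -> float:
        if dose_tol > 0:
            for ref in doses:
                if abs(d - ref) <= dose_tol:
                    return ref
        return d

    groups = []
    for d in doses:
        members = tuple(
            LitterRecord(
                rec.study_id, rec.species, d, rec.litter_id, rec.size, rec.affected
            )
            for rec in records
            if snap(rec.dose) == d
        )
        groups.append(DoseGroup(dose=d, litters=members))
    return LitterStudy(
        study_id=records[0].study_id,
        species=records[0].species,
        groups=tuple(groups),
    )


def parse_litter_table(path_or_stream, dose_tol: float = 0.0) -> LitterStudy:
    """Read a litter-level CSV (columns study,species,dose,litter,size,affected).

    Rows violating domain invariants are reported together with their line
    numbers. ``dose_tol`` > 0 merges float-formatted doses differing by at
    most that amount into one group.
    """
    df = pd.read_csv(path_or_stream)
    missing = [c for c in LITTER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"litter table is missing required column(s): {', '.join(missing)}"
        )
    return _build_study(df, dose_tol=dose_tol)


def study_to_frame(study: LitterStudy) -> pd.DataFrame:
    """Flatten a study back to the litter CSV schema."""
    rows = [
        {
            "study": rec.study_id,
            "species": rec.species,
            "dose": rec.dose,
            "litter": rec.litter_id,
            "size": rec.size,
            "affected": rec.affected,
        }
        for g in study.groups
        for rec in g.litters
    ]
    return pd.DataFrame(rows, columns=LITTER_COLUMNS)


def write_litter_table(study: LitterStudy, path_or_stream) -> None:
    """Write a study as a litter-level CSV (round-trips with the parser)."""
    study_to_frame(study).to_csv(path_or_stream, index=False)


def summaries_to_frame(
    summaries: Sequence[GroupSummary],
    design_effects: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Tabulate group summaries using the summary CSV schema."""
    rows = []
    for i, s in enumerate(summaries):
        rows.append(
            {
                "dose": s.dose,
                "n_litters": s.n_litters,
                "n_fetuses": s.n_fetuses,
                "n_affected": s.n_affected,
                "p_avg": s.p_avg,
                "sd_litter_prop": s.sd_litter_prop,
                "n_affected_litters": s.n_affected_litters,
                "design_effect": (
                    design_effects[i] if design_effects is not None else math.nan
                ),
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def read_summary_table(path_or_stream) -> list[GroupSummary]:
    """Read a dose-group summary CSV.

    Only ``dose`` plus whichever summary fields the downstream method needs
    are required; absent optional columns are filled with NaN (``n_litters``
    and ``n_affected_litters`` default to 0 when absent).
    """
    df = pd.read_csv(path_or_stream)
    if "dose" not in df.columns:
        raise SchemaError("summary table is missing required column: dose")
    out = []
    for _, row in df.sort_values("dose").iterrows():

        def get(col, default=math.nan):
            return row[col] if col in df.columns and pd.notna(row[col]) else default

        out.append(
            GroupSummary(
                dose=float(row["dose"]),
                n_fetuses=int(get("n_fetuses", 0)),
                n_affected=float(get("n_affected")),
                n_litters=int(get("n_litters", 0)),
                n_affected_litters=int(get("n_affected_litters", 0)),
                p_avg=float(get("p_avg")),
                sd_litter_prop=float(get("sd_litter_prop")),
            )
        )
    return out


def round_trip(study: LitterStudy) -> LitterStudy:
    """Write a study to CSV in memory and parse it back (identity check)."""
    buf = io.StringIO()
    write_litter_table(study, buf)
    buf.seek(0)
    return parse_litter_table(buf)
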