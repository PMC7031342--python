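"""Interactor-enrichment scoring from label-free iBAQ intensity tables.

Implements the affinity-purification MS comparison workflow: parse a
MaxQuant-style proteinGroups table (``Protein IDs`` plus per-run
``iBAQ <sample>`` columns), drop proteins detected in too few runs (default:
detected in fewer than 3 of 8 runs), average the per-run iBAQ intensities per
condition over detected runs, impute a condition average of 10 for proteins
not detected in that condition at all, and rank proteins by the
transfected/control fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class IbaqTable:
    """Protein x run iBAQ intensities with a run -> condition map.

    ``intensities`` is indexed by protein ID with one column per run; not
    detected (n.d.) is encoded as NaN, never 0.
    """

    intensities: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        missing = [r for r in self.intensities.columns if r not in self.conditions]
        if missing:
            raise ValueError(f"runs without a condition label: {missing}")

    @property
    def proteins(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def runs(self) -> list[str]:
        return list(self.intensities.columns)

    def detection_counts(self) -> pd.Series:
        """Number of runs (across all conditions) each protein was detected in."""
        return self.intensities.notna().sum(axis=1)

    def condition_runs(self, condition: str) -> list[str]:
        return [r for r in self.runs if self.conditions[r] == condition]


@dataclass(frozen=True)
class EnrichmentParams:
    """min_runs_detected: keep proteins detected in at least this many runs
    (default 3, i.e. proteins seen in only 2 or fewer of the 8 runs are
    excluded).  nd_impute_value: condition average used when a protein is not
    detected in a condition at all (default 10, raw iBAQ scale)."""

    min_runs_detected: int = 3
    nd_impute_value: float = 10.0
    total_runs_expected: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.min_runs_detected <= self.total_runs_expected:
            raise ValueError("min_runs_detected must be in (0, total_runs_expected]")
        if self.nd_impute_value <= 0:
            raise ValueError("nd_impute_value must be positive")


@dataclass
class EnrichmentResult:
    protein: str
    detected_runs: dict[str, int]
    condition_means: dict[str, float]
    fold_change: float
    imputed: dict[str, bool]

    def to_dict(self) -> dict:
        return {
            "protein": self.protein,
            **{f"n_detected_{c}": n for c, n in self.detected_runs.items()},
            **{f"mean_{c}": m for c, m in self.condition_means.items()},
            "fold_change": self.fold_change,
            **{f"imputed_{c}": v for c, v in self.imputed.items()},
        }


def parse_ibaq(
    table: str | pd.DataFrame,
    condition_map: dict[str, str] | None = None,
    protein_column: str = "Protein IDs",
) -> IbaqTable:
    """Parse a MaxQuant-style TSV (or DataFrame) into an IbaqTable.

    Intensity columns are those named ``iBAQ <sample>``; a bare aggregate
    ``iBAQ`` column is ignored.  Zeros, empty cells, and non-numeric values
    are normalized to NaN (not detected).  Without an explicit
    ``condition_map`` the condition is inferred as the sample-name prefix
    before the last underscore (``transfected_1`` -> ``transfected``).
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep="\t")
    if protein_column not in df.columns:
        raise ValueError(f"no {protein_column!r} column in table")
    ibaq_cols = [c for c in df.columns if c.startswith("iBAQ ") and c != "iBAQ"]
    if not ibaq_cols:
        raise ValueError("no 'iBAQ <sample>' columns in table")
    dup = df[protein_column][df[protein_column].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate protein IDs: {sorted(set(dup))}")
    samples = [c[len("iBAQ "):] for c in ibaq_cols]
    intensities = df[ibaq_cols].apply(pd.to_numeric, errors="coerce")
    intensities.columns = samples
    intensities.index = df[protein_column]
    intensities = intensities.mask(intensities <= 0)  # 0 means not detected
    if condition_map is None:
        condition_map = {}
        for s in samples:
            if "_" not in s:
                raise ValueError(
                    f"cannot infer condition for run {s!r}: no '_' separator; "
                    "pass an explicit condition_map"
                )
            condition_map[s] = s.rsplit("_", 1)[0]
    else:
        missing = [s for s in samples if s not in condition_map]
        if missing:
            raise ValueError(f"no condition mapping for runs: {missing}")
    return IbaqTable(intensities=intensities, conditions=dict(condition_map))


def filter_by_detection(
    table: IbaqTable, params: EnrichmentParams | None = None
) -> tuple[IbaqTable, list[str]]:
    """Drop proteins detected in fewer than ``min_runs_detected`` runs.

    Returns the filtered table and the list of excluded protein IDs.
    """
    params = params or EnrichmentParams()
    counts = table.detection_counts()
    keep = counts >= params.min_runs_detected
    excluded = list(counts.index[~keep])
    return (
        IbaqTable(intensities=table.intensities.loc[keep], conditions=table.conditions),
        excluded,
    )


def fold_change(
    table: IbaqTable,
    params: EnrichmentParams | None = None,
    numerator: str | None = None,
    denominator: str | None = None,
) -> list[EnrichmentResult]:
    """Condition-mean fold changes with n.d. imputation.

    Per condition, the mean iBAQ intensity is taken over detected runs only; a
    condition with zero detections for a protein gets its *average* replaced
    by ``nd_impute_value`` and is flagged imputed.  The fold change is
    mean(numerator)/mean(denominator).  With exactly two conditions and no
    explicit roles, the first condition in run order is the numerator.
    """
    params = params or EnrichmentParams()
    conds = list(dict.fromkeys(table.conditions[r] for r in table.runs))
    if len(conds) != 2 and (numerator is None or denominator is None):
        raise ValueError("need exactly 2 conditions (or explicit numerator/denominator)")
    if numerator is None:
        numerator, denominator = conds[0], conds[1]
    for c in (numerator, denominator):
        if c not in conds:
            raise ValueError(f"unknown condition: {c!r}")
    cond_cols = {c: table.condition_runs(c) for c in (numerator, denominator)}
    results = []
    for protein, row in table.intensities.iterrows():
        means, counts, imputed = {}, {}, {}
        for c, cols in cond_cols.items():
            vals = row[cols].dropna()
            counts[c] = int(len(vals))
            if len(vals) == 0:
                means[c] = params.nd_impute_value
                imputed[c] = True
            else:
                means[c] = float(vals.mean())
                imputed[c] = False
        results.append(
            EnrichmentResult(
                protein=str(protein),
                detected_runs=counts,
                condition_means=means,
                fold_change=means[numerator] / means[denominator],
                imputed=imputed,
            )
        )
    results.sort(key=lambda r: r.fold_change, reverse=True)
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
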