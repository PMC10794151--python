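"""Three-criterion secretome candidate screen over PSM abundance tables.

Candidates must (1) have a molecular weight inside one of the fraction
windows (10-30 or 30-100 kDa, closed bounds; a protein sitting exactly on
the shared 30 kDa cut is assigned by its declared fraction label),
(2) be unique to, or more than twofold enriched in, BOTH treated conditions
relative to vehicle, and (3) carry the secreted annotation.  The screen is a
deterministic filter - no normalization, no significance testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .model import ValidationError

__all__ = ["enrichment_status", "apply_candidate_filter", "CandidateList",
           "PSM_COLUMNS", "read_psm_table", "write_psm_table"]

PSM_COLUMNS = ["protein_id", "gene", "mw_kda", "secreted", "fraction",
               "psm_vehicle", "psm_pf", "psm_protx"]
MW_WINDOWS = ((10.0, 30.0), (30.0, 100.0))
FRACTION_LABELS = {"10-30": (10.0, 30.0), "30-100": (30.0, 100.0)}


@dataclass
class CandidateList:
    table: pd.DataFrame  # passing rows, deterministic order
    reasons: list[dict]  # per-row reason codes

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()


def enrichment_status(psm_vehicle: int, psm_treated: int) -> tuple[str, float | None]:
    """Classify one vehicle/treated PSM pair.

    Returns ``("unique", None)``, ``("fold", value)`` with enrichment iff
    the fold change strictly exceeds 2, or ``("not_enriched", None)``.
    """
    if psm_vehicle < 0 or psm_treated < 0:
        raise ValidationError("PSM counts must be >= 0")
    if psm_vehicle == 0:
        return ("unique", None) if psm_treated > 0 else ("not_enriched", None)
    return "fold", psm_treated / psm_vehicle


def _is_enriched(psm_vehicle: int, psm_treated: int) -> tuple[bool, str]:
    status, fold = enrichment_status(psm_vehicle, psm_treated)
    if status == "unique":
        return True, "unique"
    if status == "fold" and fold > 2.0:
        return True, f"fold={fold:.3g}"
    return False, "not_enriched"


def _mw_passes(mw: float, fraction: str,
               windows: tuple[tuple[float, float], ...]) -> bool:
    # boundary exactly shared by two windows: the declared fraction decides
    hits = [w for w in windows if w[0] <= mw <= w[1]]
    if len(hits) > 1 and fraction in FRACTION_LABELS:
        return FRACTION_LABELS[fraction] in hits
    return bool(hits)


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in PSM_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"PSM table missing columns: {missing}")
    for idx, row in table.iterrows():
        for col in ("psm_vehicle", "psm_pf", "psm_protx"):
            v = row[col]
            if pd.isna(v) or v < 0 or int(v) != v:
                raise ValidationError(
                    f"row {row['protein_id']!r}: {col} must be a "
                    f"non-negative integer, got {v!r}")
        if not row["mw_kda"] > 0:
            raise ValidationError(
                f"row {row['protein_id']!r}: molecular weight must be > 0")
        frac = row["fraction"]
        if frac in FRACTION_LABELS:
            lo, hi = FRACTION_LABELS[frac]
            if not (lo <= row["mw_kda"] <= hi):
                warnings.warn(
                    f"row {row['protein_id']!r}: MW {row['mw_kda']} kDa "
                    f"outside declared fraction {frac} kDa", RuntimeWarning)


def apply_candidate_filter(table: pd.DataFrame,
                           mw_windows: tuple[tuple[float, float], ...] = MW_WINDOWS,
                           ) -> CandidateList:
    """Apply the three-criterion screen; empty tables yield empty lists."""
    if table.empty:
        return CandidateList(table=table.copy(), reasons=[])
    _validate_table(table)
    keep_idx = []
    reasons = []
    for idx, row in table.iterrows():
        if not _mw_passes(float(row["mw_kda"]), str(row["fraction"]), mw_windows):
            continue
        pf_ok, pf_reason = _is_enriched(int(row["psm_vehicle"]), int(row["psm_pf"]))
        protx_ok, protx_reason = _is_enriched(int(row["psm_vehicle"]),
                                              int(row["psm_protx"]))
        if not (pf_ok and protx_ok):
            continue
        if not bool(row["secreted"]):
            continue
        keep_idx.append(idx)
        reasons.append({"protein_id": row["protein_id"],
                        "pf": pf_reason, "protx": protx_reason})
    out = table.loc[keep_idx].copy()
    out["combined_psm"] = out["psm_pf"] + out["psm_protx"]
    out = out.sort_values(["combined_psm", "protein_id"],
                          ascending=[False, True]).drop(columns="combined_psm")
    order = {pid: i for i, pid in enumerate(out["protein_id"])}
    reasons.sort(key=lambda r: order[r["protein_id"]])
    return CandidateList(table=out.reset_index(drop=True), reasons=reasons)


def packaged_psm_fixture() -> pd.DataFrame:
    """The shipped PSM fixture table (regenerable via the CLI or
    :func:`navclamp.synth.generate_psm_fixture` with seed 0)."""
    from importlib.resources import files
    with (files("navclamp") / "data" / "psm_fixture.tsv").open() as fh:
        return read_psm_table(fh)


def read_psm_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "secreted" in df.columns:
        df["secreted"] = df["secreted"].astype(bool)
    return df


def write_psm_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
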