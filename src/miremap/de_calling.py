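"""Fold-change differential-expression calling and cross-platform intersection.

The DE criterion is fold change only: >= 1.5 up, <= 0.66 down (inclusive),
applied per platform; the high-confidence set is the direction-consistent
intersection of both platforms.  No replicate-based testing is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ParseError
from .interaction_db import MirnaLocus

UP = "up"
DOWN = "down"
NONE = "none"


@dataclass(frozen=True)
class DEConfig:
    up_threshold: float = 1.5
    down_threshold: float = 0.66
    ct_min: float = 15.0
    ct_max: float = 35.0
    control_id: str = "U6"

    def __post_init__(self) -> None:
        if not (self.down_threshold < 1.0 < self.up_threshold):
            raise ConfigError("need down_threshold < 1 < up_threshold")
        if self.ct_min >= self.ct_max:
            raise ConfigError("need ct_min < ct_max")


@dataclass(frozen=True)
class DECall:
    """Direction call for one molecule on one platform."""

    molecule: str
    fc: float
    direction: str
    platform: str = ""


@dataclass(frozen=True)
class HighConfidenceDEmiR:
    """A miRNA called DE in the same direction on both platforms."""

    mirna: str
    direction: str
    fc_seq: float
    fc_array: float
    locus: MirnaLocus | None = None


def classify_fc(fc: float, cfg: DEConfig) -> str:
    if not np.isfinite(fc) or fc <= 0:
        raise ConfigError(f"fold change must be finite and positive, got {fc}")
    if fc >= cfg.up_threshold:
        return UP
    if fc <= cfg.down_threshold:
        return DOWN
    return NONE


def call_de(fc_table: pd.DataFrame, cfg: DEConfig | None = None,
            platform: str = "", id_col: str | None = None,
            fc_col: str = "fc") -> list[DECall]:
    """Apply the fold-change thresholds to a (id, fc) table.

    ``fc_table`` needs an identifier column (first column by default) and a
    fold-change column named ``fc_col``.
    """
    cfg = cfg or DEConfig()
    id_col = id_col or fc_table.columns[0]
    calls = []
    for row in fc_table.itertuples(index=False):
        fc = float(getattr(row, fc_col))
        calls.append(DECall(str(getattr(row, id_col)), fc,
                            classify_fc(fc, cfg), platform))
    return calls


# genes use the same thresholds and machinery as miRNAs
call_de_genes = call_de


def _quantile_normalize(mat: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization; for two samples this is rank-wise mean
    substitution.  Tied values within a column share the reference value of
    their lowest rank."""
    reference = pd.Series(
        np.sort(mat.values, axis=0).mean(axis=1),
        index=np.arange(1, len(mat) + 1),
    )
    out = mat.copy()
    for col in mat.columns:
        out[col] = mat[col].rank(method="min").astype(int).map(reference).to_numpy()
    return out


def normalize_openarray(ct_table: pd.DataFrame, cfg: DEConfig | None = None,
                        wt: str = "WT", ko: str = "KO",
                        quantile: bool = True) -> pd.DataFrame:
    """Ct table -> per-miRNA fold changes via 2^(-ddCt) against the control.

    Input: long table with columns (mirna, well, sample, Ct); the string
    ``"Undetermined"`` is accepted as a missing Ct.  Processing order:

    1. undetermined wells -> NaN;
    2. technical duplicates averaged per (mirna, sample);
    3. miRNAs whose Ct is missing or outside [ct_min, ct_max] in *all*
       samples are removed; miRNAs with any remaining missing sample are
       dropped as uncomputable;
    4. columns quantile-normalized (rank-wise mean for two samples);
    5. dCt vs the control row per sample, ddCt = dCt_KO - dCt_WT,
       FC = 2^(-ddCt).

    Returns a (mirna, fc) frame excluding the control itself.
    """
    cfg = cfg or DEConfig()
    required = {"mirna", "sample", "Ct"}
    if not required <= set(ct_table.columns):
        raise ParseError(f"Ct table needs columns {sorted(required)}")
    df = ct_table.copy()
    df["Ct"] = pd.to_numeric(df["Ct"], errors="coerce")  # "Undetermined" -> NaN

    samples = list(dict.fromkeys(df["sample"]))
    if len(samples) < 2:
        raise ConfigError("OpenArray normalization requires two samples (WT, KO)")
    for s in (wt, ko):
        if s not in samples:
            raise ConfigError(f"sample {s!r} absent from Ct table")

    mat = df.groupby(["mirna", "sample"])["Ct"].mean().unstack("sample")[[wt, ko]]

    # range filter applies to miRNAs, never to the endogenous control
    is_control = mat.index == cfg.control_id
    in_range = mat.ge(cfg.ct_min) & mat.le(cfg.ct_max)
    mat = mat[in_range.any(axis=1) | is_control]  # out of range across all samples
    mat = mat.dropna()                            # uncomputable fold change

    if cfg.control_id not in mat.index:
        raise ConfigError(
            f"control {cfg.control_id!r} missing from Ct table after filtering"
        )
    if quantile:
        mat = _quantile_normalize(mat)

    dct = mat.sub(mat.loc[cfg.control_id], axis=1)
    ddct = dct[ko] - dct[wt]
    fc = np.power(2.0, -ddct)
    fc = fc.drop(index=cfg.control_id)
    return pd.DataFrame({"mirna": fc.index, "fc": fc.to_numpy()}).reset_index(drop=True)


def seq_fold_changes(count_table: pd.DataFrame, wt: str = "WT", ko: str = "KO",
                     pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-miRNA fold change from a long count table (mirna, sample, count).

    Counts are library-proportion normalized; a pseudocount on raw counts
    keeps zero-count miRNAs finite.  FC = (KO proportion) / (WT proportion).
    """
    required = {"mirna", "sample", "count"}
    if not required <= set(count_table.columns):
        raise ParseError(f"count table needs columns {sorted(required)}")
    mat = count_table.groupby(["mirna", "sample"])["count"].sum().unstack("sample")
    for s in (wt, ko):
        if s not in mat.columns:
            raise ConfigError(f"sample {s!r} absent from count table")
        if mat[s].sum() <= 0:
            raise ConfigError(f"zero library size for sample {s!r}")
    adj = mat[[wt, ko]].fillna(0.0) + pseudocount
    prop = adj / adj.sum(axis=0)
    fc = prop[ko] / prop[wt]
    return pd.DataFrame({"mirna": fc.index, "fc": fc.to_numpy()}).reset_index(drop=True)


def intersect_platforms(
    calls_seq: Iterable[DECall], calls_array: Iterable[DECall],
    loci: dict[str, MirnaLocus] | None = None,
) -> tuple[list[HighConfidenceDEmiR], list[str]]:
    """Direction-consistent intersection of two platforms' DE calls.

    A miRNA is retained iff it is called non-none on both platforms with the
    same direction.  Returns (retained, conflicts) where ``conflicts`` lists
    miRNAs DE on both platforms but in opposite directions.
    """
    seq = {c.molecule: c for c in calls_seq}
    arr = {c.molecule: c for c in calls_array}
    retained: list[HighConfidenceDEmiR] = []
    conflicts: list[str] = []
    for name in sorted(seq.keys() & arr.keys()):
        a, b = seq[name], arr[name]
        if a.direction == NONE or b.direction == NONE:
            continue
        if a.direction != b.direction:
            conflicts.append(name)
            continue
        retained.append(
            HighConfidenceDEmiR(
                mirna=name, direction=a.direction, fc_seq=a.fc, fc_array=b.fc,
                locus=(loci or {}).get(name),
            )
        )
    return retained, conflicts


def de_calls_frame(calls: Sequence[DECall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": c.molecule, "fc": c.fc, "direction": c.direction,
          "platform": c.platform} for c in calls],
        columns=["id", "fc", "direction", "platform"],
    )
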