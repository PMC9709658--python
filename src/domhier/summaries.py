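"""Outcome statistics: reproductive skew, per-rank summaries, TSV writers.

The skew index M measures inequality of reproductive success within a group,
corrected for the sampling noise of a finite number of offspring: a
multinomially random equal allocation has expectation ~0 and a complete
monopoly gives 1 - 1/O (O = total offspring).  With shares s_k = counts/O
over n survivors,

    M = [sum s_k^2 - 1/n - (1 - 1/n)/O] / (1 - 1/n).

Per-rank tables aggregate over simulated groups (survivors only, since only
survivors hold a dominance position): mean reproductive success by rank,
damage quartiles by rank, the distribution of M over groups, the group AR
decomposition, and the raw per-individual fight counts by rank.  Quartiles
use the linear-interpolation convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["skew_index_M", "skew_index_M_groups", "GroupRecord",
           "SummaryTables", "per_rank_summaries", "write_outputs", "read_outputs"]


def skew_index_M(offspring_counts) -> float:
    """Multinomial-corrected skew index of one group's offspring counts.

    Requires at least two survivors and at least one offspring in total;
    otherwise the index is undefined and NaN is returned.
    """
    counts = np.asarray(offspring_counts, dtype=float)
    n = counts.size
    O = counts.sum()
    if n < 2 or O < 1:
        return float("nan")
    shares = counts / O
    return float((np.sum(shares ** 2) - 1.0 / n - (1.0 - 1.0 / n) / O) / (1.0 - 1.0 / n))


def skew_index_M_groups(counts: np.ndarray, alive: np.ndarray) -> np.ndarray:
    """Vectorized M over a batch of groups: counts and alive are (G, S).

    Only survivors' counts enter; groups with fewer than two survivors or
    zero offspring get NaN.
    """
    counts = np.where(alive, np.asarray(counts, dtype=float), 0.0)
    n = np.asarray(alive, dtype=bool).sum(axis=1)
    O = counts.sum(axis=1)
    ok = (n >= 2) & (O >= 1)
    out = np.full(counts.shape[0], np.nan)
    if ok.any():
        Ok, nk = O[ok], n[ok]
        shares = counts[ok] / Ok[:, None]
        ss = (shares ** 2).sum(axis=1)
        out[ok] = (ss - 1.0 / nk - (1.0 - 1.0 / nk) / Ok) / (1.0 - 1.0 / nk)
    return out


@dataclass
class GroupRecord:
    """Per-group, per-generation raw outcome (survivors only).

    Arrays are aligned over the group's survivors; ``decomposition`` is the
    (remaining, lost_interference, lost_damage) AR triple as proportions of
    the maximal group AR.
    """

    ranks: np.ndarray          # recompacted survivor ranks, 1..n_survivors
    rs: np.ndarray             # realized offspring counts
    damage: np.ndarray
    aa_rounds: np.ndarray
    M: float
    decomposition: np.ndarray  # (3,)
    generation: int = -1
    group: int = -1


@dataclass
class SummaryTables:
    """Tidy outcome tables aggregated over groups.

    per_rank: rank, n, mean_rs, damage_q1/median/q3;
    skew: quartiles of M over groups;
    groups_ar: mean AR decomposition;
    fights: one row per surviving individual (rank, aa_rounds).
    """

    per_rank: pd.DataFrame
    skew: pd.DataFrame
    groups_ar: pd.DataFrame
    fights: pd.DataFrame


def _quartiles(x: np.ndarray):
    if x.size == 0:
        return (np.nan, np.nan, np.nan)
    return tuple(np.percentile(x, [25, 50, 75], method="linear"))


def per_rank_summaries(records: Sequence[GroupRecord]) -> SummaryTables:
    """Aggregate group records into the standard outcome tables.

    Dead individuals never appear (a record holds survivors only), so a
    group with three deaths contributes five rank entries.
    """
    if len(records) == 0:
        raise ValueError("need at least one group record")
    ranks = np.concatenate([r.ranks for r in records]) if records else np.array([])
    rs = np.concatenate([r.rs for r in records])
    dmg = np.concatenate([r.damage for r in records])
    aa = np.concatenate([r.aa_rounds for r in records])

    rows = []
    for k in np.unique(ranks):
        sel = ranks == k
        q1, med, q3 = _quartiles(dmg[sel])
        rows.append({
            "rank": int(k), "n": int(sel.sum()),
            "mean_rs": float(rs[sel].mean()),
            "damage_q1": q1, "damage_median": med, "damage_q3": q3,
        })
    per_rank = pd.DataFrame(rows, columns=["rank", "n", "mean_rs",
                                           "damage_q1", "damage_median", "damage_q3"])

    m = np.array([r.M for r in records], dtype=float)
    m = m[~np.isnan(m)]
    q1, med, q3 = _quartiles(m)
    skew = pd.DataFrame([{"n_groups": len(records), "M_q1": q1,
                          "M_median": med, "M_q3": q3}])

    dec = np.array([r.decomposition for r in records], dtype=float)
    groups_ar = pd.DataFrame([{
        "remaining": float(dec[:, 0].mean()),
        "lost_interference": float(dec[:, 1].mean()),
        "lost_damage": float(dec[:, 2].mean()),
    }])

    fights = pd.DataFrame({
        "rank": ranks.astype(int),
        "aa_rounds": aa.astype(int),
    })
    return SummaryTables(per_rank=per_rank, skew=skew, groups_ar=groups_ar, fights=fights)


_FILES = {
    "per_rank": "per_rank.tsv",
    "skew": "skew.tsv",
    "groups_ar": "groups_ar.tsv",
    "fights": "fights.tsv",
}


def write_outputs(tables: SummaryTables, out_dir: Union[str, Path]) -> List[Path]:
    """Write the four tables as TSV ('.' decimal, NA for undefined values).

    Column order is fixed by the table constructors, so files are stable
    across runs with identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for attr, fname in _FILES.items():
        path = out_dir / fname
        getattr(tables, attr).to_csv(path, sep="\t", index=False, na_rep="NA")
        written.append(path)
    return written


def read_outputs(out_dir: Union[str, Path]) -> SummaryTables:
    """Inverse of :func:`write_outputs` (round-trips the tables)."""
    out_dir = Path(out_dir)
    frames = {attr: pd.read_csv(out_dir / fname, sep="\t")
              for attr, fname in _FILES.items()}
    return SummaryTables(**frames)
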