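"""Agreement statistics between automated detections and manual ratings.

Cohen's Kappa for per-subject microbleed presence, a two-way
random-effects absolute-agreement single-measure ICC (ICC(2,1)) for
counts, Kappa interpretation bands (poor/fair/moderate/good/excellent),
and greedy centroid matching of detections against a reference lesion
list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KAPPA_BANDS = (
    (0.2, "poor"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "good"),
    (np.inf, "excellent"),
)


def cohen_kappa(a, b) -> float:
    """Cohen's Kappa for two binary ratings of the same subjects.

    kappa = (p_o - p_e) / (1 - p_e).  When both raters are constant and
    identical, agreement is perfect and kappa is defined as 1; constant
    chance agreement with any disagreement is undefined and returns NaN.
    """
    a = np.asarray(a).astype(int).ravel()
    b = np.asarray(b).astype(int).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("ratings must have equal length >= 2")
    n = a.size
    po = float(np.mean(a == b))
    cats = np.union1d(a, b)
    pe = float(
        sum(np.mean(a == c) * np.mean(b == c) for c in cats)
    )
    if pe >= 1.0 - 1e-12:
        return 1.0 if po >= 1.0 - 1e-12 else float("nan")
    return (po - pe) / (1.0 - pe)


def interpret_kappa(k: float) -> str:
    """Interpretation band for a Kappa value (cut points 0.2/0.4/0.6/0.8;
    a boundary value belongs to the upper band)."""
    if not (-1.0 - 1e-9 <= k <= 1.0 + 1e-9):
        raise ValueError("kappa must lie in [-1, 1]")
    for cut, label in KAPPA_BANDS:
        if k < cut:
            return label
    return "excellent"


def icc_counts(a, b) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measure — the standard choice for method-versus-reference counts.

    Computed from the mean-squares decomposition of the n x 2 table;
    returns NaN when there is no variance at all.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape or a.size < 3:
        raise ValueError("count lists must have equal length >= 3")
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-12:
        return float("nan")
    return float((msr - mse) / denom)


@dataclass
class MatchResult:
    """One-to-one lesion matching between detections and a reference."""

    tp: int
    fp: int
    fn: int
    pairs: list  # (auto_index, ref_index, distance_mm)

    @property
    def sensitivity(self) -> float:
        total = self.tp + self.fn
        return self.tp / total if total else float("nan")


def match_detections(auto_centroids, reference_centroids, tol_mm: float = 5.0) -> MatchResult:
    """Greedy nearest-centroid one-to-one matching under ``tol_mm``.

    Accepts centroid arrays (n, 3) in a common space, or objects with a
    ``centroid_mm`` attribute.  TP + FN = |reference|; TP + FP = |auto|.
    """

    def _coords(items):
        out = []
        for it in items:
            out.append(
                np.asarray(getattr(it, "centroid_mm", it), float)
            )
        return np.asarray(out).reshape(-1, 3) if out else np.empty((0, 3))

    A = _coords(list(auto_centroids))
    R = _coords(list(reference_centroids))
    if len(A) == 0 or len(R) == 0:
        return MatchResult(tp=0, fp=len(A), fn=len(R), pairs=[])
    d = np.linalg.norm(A[:, None, :] - R[None, :, :], axis=2)
    pairs = []
    used_a: set[int] = set()
    used_r: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for ia, ir in order:
        if d[ia, ir] > tol_mm:
            break
        if ia in used_a or ir in used_r:
            continue
        used_a.add(int(ia))
        used_r.add(int(ir))
        pairs.append((int(ia), int(ir), float(d[ia, ir])))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(A) - tp, fn=len(R) - tp, pairs=pairs)


def rating_table(records) -> pd.DataFrame:
    """Normalise per-subject, per-region count records into a table with
    columns subject, region, count; presence = (count > 0)."""
    df = pd.DataFrame(records)
    required = {"subject", "region", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"rating table needs columns {sorted(required)}")
    if (df["count"] < 0).any():
        raise ValueError("counts must be >= 0")
    df["presence"] = df["count"] > 0
    return df


def agreement_summary(auto: pd.DataFrame, manual: pd.DataFrame) -> dict:
    """Presence Kappa and count ICC per region, plus the multi-CMB
    (>= 2 lobar lesions) dichotomy, for two rating tables."""
    auto = rating_table(auto)
    manual = rating_table(manual)
    merged = auto.merge(
        manual, on=["subject", "region"], suffixes=("_auto", "_manual")
    )
    out = {}
    for region, grp in merged.groupby("region"):
        if len(grp) < 3:
            continue
        kappa = cohen_kappa(grp["presence_auto"], grp["presence_manual"])
        out[region] = {
            "kappa": kappa,
            "kappa_band": interpret_kappa(kappa) if np.isfinite(kappa) else "undefined",
            "icc": icc_counts(grp["count_auto"], grp["count_manual"]),
            "n_subjects": int(len(grp)),
        }
    lob = merged[merged["region"] == "lobar"]
    if len(lob) >= 2:
        multi_a = (lob["count_auto"] >= 2).to_numpy()
        multi_m = (lob["count_manual"] >= 2).to_numpy()
        kappa = cohen_kappa(multi_a, multi_m)
        out["multi_cmb_lobar"] = {
            "kappa": kappa,
            "kappa_band": interpret_kappa(kappa) if np.isfinite(kappa) else "undefined",
            "n_subjects": int(len(lob)),
        }
    return out
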