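"""Descriptive statistics, hub identification, intake summaries and exports.

Covers the reporting layer around the network test: node degree and hub
ranking within significant components, BrainNet Viewer ``.node``/``.edge``
file export, group comparisons of demographic/outcome variables with
normality-driven test dispatch, postnatal nutrient-intake summaries over days
9–29, and participant-flow (attrition) accounting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import AtlasInfo
from .nbs import ComponentResult, NBSResults

__all__ = [
    "node_degree",
    "identify_hubs",
    "export_brainnet",
    "read_brainnet",
    "compare_demographics",
    "summarize_intake",
    "summarize_attrition",
    "DEFAULT_RECOMMENDATIONS",
    "INTAKE_WINDOW",
]

# enteral intake recommendations: protein/lipid/carbohydrate in g/kg/day,
# energy in kcal/kg/day
DEFAULT_RECOMMENDATIONS: dict[str, float] = {
    "protein": 3.5,
    "lipid": 4.8,
    "carbohydrate": 11.6,
    "energy": 110.0,
}
INTAKE_WINDOW: tuple[int, int] = (9, 29)  # postnatal days, inclusive


def node_degree(component: ComponentResult) -> dict[int, int]:
    """Edge count incident to each node within one component.

    The degrees satisfy the handshake lemma: Σ degree = 2 × extent.
    """
    degrees: dict[int, int] = {n: 0 for n in component.nodes}
    for i, j in component.edges:
        degrees[i] += 1
        degrees[j] += 1
    return degrees


def identify_hubs(
    degrees: dict[int, int], top_k: int, atlas: AtlasInfo | None = None
) -> list[tuple[str, int, int]]:
    """Rank regions by degree descending; ties broken by label lexicographic.

    Returns up to ``top_k`` tuples of (label, region_index, degree).  Without
    an atlas the label is the zero-padded region index.
    """
    if not degrees:
        raise ValueError("empty degree map")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    label = (
        (lambda r: atlas.labels[r]) if atlas is not None else (lambda r: f"region_{r:03d}")
    )
    ranked = sorted(degrees.items(), key=lambda kv: (-kv[1], label(kv[0])))
    return [(label(r), r, d) for r, d in ranked[:top_k]]


def export_brainnet(
    result: NBSResults | ComponentResult,
    atlas: AtlasInfo,
    node_path,
    edge_path,
    component: int = 0,
    weights: str = "binary",
) -> None:
    """Write BrainNet Viewer ``.node`` and ``.edge`` files for one component.

    ``.node``: one whitespace-delimited row per atlas region — x y z colour
    size label — where colour is 1 for component members (else 0) and size is
    the node degree within the component ("node size scaled by degree").
    ``.edge``: the full square adjacency matrix, 1/0 membership by default or
    the edge t values with ``weights="t"`` (requires an NBSResults input).
    """
    if isinstance(result, NBSResults):
        comp = result.components[component]
        t_matrix = result.edge_stats.t_values
    else:
        comp = result
        t_matrix = None
    if comp.nodes and max(comp.nodes) >= atlas.n_regions:
        raise ValueError(
            f"component references region {max(comp.nodes)} not covered by the "
            f"{atlas.n_regions}-region atlas"
        )
    degrees = node_degree(comp)
    with open(node_path, "w") as fh:
        for r in range(atlas.n_regions):
            x, y, z = atlas.coords[r]
            colour = 1 if r in comp.nodes else 0
            size = degrees.get(r, 0)
            fh.write(f"{x:g}\t{y:g}\t{z:g}\t{colour}\t{size}\t{atlas.labels[r]}\n")
    A = np.zeros((atlas.n_regions, atlas.n_regions))
    for i, j in comp.edges:
        if weights == "t":
            if t_matrix is None:
                raise ValueError("t-weighted export requires an NBSResults input")
            val = t_matrix[i, j]
        else:
            val = 1.0
        A[i, j] = A[j, i] = val
    np.savetxt(edge_path, A, fmt="%.17g", delimiter="\t")


def read_brainnet(node_path, edge_path):
    """Parse BrainNet files written by :func:`export_brainnet`.

    Returns (atlas, colours, sizes, adjacency).
    """
    coords, colours, sizes, labels = [], [], [], []
    with open(node_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            coords.append([float(v) for v in parts[:3]])
            colours.append(int(float(parts[3])))
            sizes.append(int(float(parts[4])))
            labels.append(parts[5])
    atlas = AtlasInfo(labels=labels, coords=np.asarray(coords))
    A = np.atleast_2d(np.loadtxt(edge_path))
    if A.shape != (atlas.n_regions, atlas.n_regions):
        raise ValueError("edge matrix shape does not match node file")
    return atlas, np.asarray(colours), np.asarray(sizes), A


@dataclass
class DemographicsReport:
    """Per-variable group-comparison results with the dispatch rationale."""

    table: pd.DataFrame

    def __str__(self) -> str:
        return self.table.to_string(index=False)


def _fmt_normal(x: np.ndarray) -> str:
    return f"{np.mean(x):.1f} ± {np.std(x, ddof=1):.1f}"


def _fmt_nonnormal(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:g} {{{q1:g}, {q3:g}}}"


def compare_demographics(
    cohort: pd.DataFrame,
    variables: dict[str, str],
    group_col: str = "group",
    shapiro_alpha: float = 0.05,
) -> DemographicsReport:
    """Two-group comparisons with normality-driven test dispatch.

    Categorical variables: Pearson chi-square on the contingency table,
    without continuity correction.  Continuous variables: Shapiro-Wilk per
    group at ``shapiro_alpha``; if both groups are consistent with normality a
    two-tailed pooled-variance t-test is used (summary mean ± SD), otherwise a
    two-sided Mann-Whitney U (summary median {IQR}).  A group with fewer than
    3 continuous observations skips the variable with a warning.
    """
    groups = sorted(cohort[group_col].dropna().astype(str).unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    ga, gb = groups
    rows = []
    for var, kind in variables.items():
        sub = cohort[[group_col, var]].dropna()
        if kind == "categorical":
            table = pd.crosstab(sub[group_col].astype(str), sub[var])
            stat, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
            counts = {
                g: "/".join(str(v) for v in table.loc[g].tolist()) for g in groups
            }
            rows.append(
                {
                    "variable": var,
                    "test": "chi-square",
                    "statistic": stat,
                    "df": dof,
                    "p_value": p,
                    f"summary_{ga}": counts[ga],
                    f"summary_{gb}": counts[gb],
                }
            )
        elif kind == "continuous":
            xa = sub.loc[sub[group_col].astype(str) == ga, var].to_numpy(dtype=float)
            xb = sub.loc[sub[group_col].astype(str) == gb, var].to_numpy(dtype=float)
            if len(xa) < 3 or len(xb) < 3:
                warnings.warn(
                    f"variable {var!r} skipped: a group has < 3 observations",
                    stacklevel=2,
                )
                continue
            normal = (
                stats.shapiro(xa).pvalue > shapiro_alpha
                and stats.shapiro(xb).pvalue > shapiro_alpha
            )
            if normal:
                res = stats.ttest_ind(xa, xb, equal_var=True)
                rows.append(
                    {
                        "variable": var,
                        "test": "t-test",
                        "statistic": float(res.statistic),
                        "df": len(xa) + len(xb) - 2,
                        "p_value": float(res.pvalue),
                        f"summary_{ga}": _fmt_normal(xa),
                        f"summary_{gb}": _fmt_normal(xb),
                    }
                )
            else:
                res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
                rows.append(
                    {
                        "variable": var,
                        "test": "mann-whitney",
                        "statistic": float(res.statistic),
                        "df": np.nan,
                        "p_value": float(res.pvalue),
                        f"summary_{ga}": _fmt_nonnormal(xa),
                        f"summary_{gb}": _fmt_nonnormal(xb),
                    }
                )
        else:
            raise ValueError(f"variable {var!r}: unknown kind {kind!r}")
    cols = ["variable", "test", "statistic", "df", "p_value", f"summary_{ga}", f"summary_{gb}"]
    return DemographicsReport(table=pd.DataFrame(rows, columns=cols))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_intake(
    intake: pd.DataFrame,
    window: tuple[int, int] = INTAKE_WINDOW,
    recommendations: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject day-window intake means plus cohort achievement summary.

    ``intake`` is long format with columns subject_id, postnatal_day,
    nutrient, value.  For each subject and nutrient the arithmetic mean over
    postnatal days ``window`` (inclusive; default 9–29) is computed — values
    outside the window never enter the mean, and missing days inside it are
    logged and excluded.  The achievement flag is mean ≥ recommendation.
    Cohort summary reports mean (SD) and achieved n (%) with percentages
    rounded half away from zero.
    """
    if recommendations is None:
        recommendations = DEFAULT_RECOMMENDATIONS
    required = {"subject_id", "postnatal_day", "nutrient", "value"}
    if not required.issubset(intake.columns):
        raise ValueError(f"intake table must have columns {sorted(required)}")
    if (intake["value"] < 0).any():
        bad = intake[intake["value"] < 0].iloc[0]
        raise ValueError(
            f"negative intake value {bad['value']} for subject {bad['subject_id']}"
        )
    lo, hi = window
    win = intake[(intake["postnatal_day"] >= lo) & (intake["postnatal_day"] <= hi)]
    n_days_expected = hi - lo + 1
    per_rows = []
    for (sid, nutrient), grp in win.groupby(["subject_id", "nutrient"], sort=True):
        n_days = grp["postnatal_day"].nunique()
        if n_days < n_days_expected:
            warnings.warn(
                f"subject {sid} nutrient {nutrient}: only {n_days} of "
                f"{n_days_expected} window days present; mean over available days",
                stacklevel=2,
            )
        mean_val = float(grp["value"].mean())
        rec = recommendations.get(nutrient)
        per_rows.append(
            {
                "subject_id": sid,
                "nutrient": nutrient,
                "mean_intake": mean_val,
                "n_days_used": n_days,
                "recommendation": rec,
                "achieved": bool(mean_val >= rec) if rec is not None else np.nan,
            }
        )
    per_subject = pd.DataFrame(per_rows)
    cohort_rows = []
    for nutrient, grp in per_subject.groupby("nutrient", sort=True):
        vals = grp["mean_intake"].to_numpy()
        rec = recommendations.get(nutrient)
        n = len(grp)
        if rec is not None:
            n_ach = int(grp["achieved"].sum())
            pct = _round_half_away(100.0 * n_ach / n)
        else:
            n_ach, pct = np.nan, np.nan
        cohort_rows.append(
            {
                "nutrient": nutrient,
                "n": n,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if n > 1 else np.nan,
                "recommendation": rec,
                "n_achieved": n_ach,
                "pct_achieved": pct,
            }
        )
    return per_subject, pd.DataFrame(cohort_rows)


def summarize_attrition(flow: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Participant-flow accounting from per-subject exclusion reasons.

    ``flow`` has one row per recruited subject with columns ``group`` and
    ``exclusion_reason`` (empty/NaN for analysed subjects).  Returns per-group
    recruited, per-reason exclusion counts and the analysed n.
    """
    rows = []
    for g, grp in flow.groupby(group_col, sort=True):
        reasons = grp["exclusion_reason"].fillna("").astype(str)
        excluded = reasons[reasons != ""]
        row = {"group": g, "recruited": len(grp), "analysed": int((reasons == "").sum())}
        for reason, cnt in excluded.value_counts().items():
            row[f"excluded_{reason}"] = int(cnt)
        rows.append(row)
    return pd.DataFrame(rows).fillna(0)
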