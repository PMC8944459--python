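"""Per-stay synoptic tables joining therapy and monitoring cluster labels.

The stay table has one row per treated patient-day: the therapy cluster id and
24 hourly cells.  Hourly cells store ``monitoring_cluster_id + 1`` so that 0
unambiguously marks an hour without monitoring (cluster ids are 0-based, so the
raw id 0 would collide with "absent"); report labels map cell c > 0 back to
monitoring cluster c - 1.

From the stay table the module derives the summary artifacts: per-cluster
fuzzy-subset frequency tables, the therapy x monitoring contingency table
(cells as fractions of the grand total over monitored hours), Pearson
chi-square tests on the raw counts, the per-stay count of distinct therapy
clusters (Nabtcl) with its stratified tables, and per-patient charts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "HOUR_COLUMNS",
    "build_stay_table",
    "subset_frequencies",
    "contingency",
    "ContingencyTable",
    "chi_square",
    "nabtcl_summary",
    "NabtclSummary",
    "extract_stay_window",
    "stay_chart",
    "plot_fuzzified_ribbon",
]

HOUR_COLUMNS: tuple[str, ...] = tuple(f"h{h:02d}" for h in range(24))


def build_stay_table(therapy_labels: pd.DataFrame, monitoring_labels: pd.DataFrame) -> pd.DataFrame:
    """Join per-day therapy clusters with per-hour monitoring clusters.

    ``therapy_labels``: patient_id, date, cluster.  ``monitoring_labels``:
    patient_id, date, hour, cluster.  Only patient-days with a therapy label
    are retained (the analysis population is treated patients); hours without
    monitoring are 0.  Rows are ordered chronologically within patient.
    """
    t = therapy_labels.loc[:, ["patient_id", "date", "cluster"]].rename(columns={"cluster": "therapy_cluster"}).copy()
    t["date"] = pd.to_datetime(t["date"]).dt.normalize()

    m = monitoring_labels.loc[:, ["patient_id", "date", "hour", "cluster"]].copy()
    m["date"] = pd.to_datetime(m["date"]).dt.normalize()
    m["cell"] = m["cluster"].astype(np.int64) + 1
    wide = (
        m.pivot_table(index=["patient_id", "date"], columns="hour", values="cell", aggfunc="first")
        .reindex(columns=range(24))
        .rename(columns={h: HOUR_COLUMNS[h] for h in range(24)})
    )

    out = t.merge(wide.reset_index(), on=["patient_id", "date"], how="left")
    out[list(HOUR_COLUMNS)] = out[list(HOUR_COLUMNS)].fillna(0).astype(np.int64)
    return out.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)


def subset_frequencies(labels, patterns) -> pd.DataFrame:
    """Per-cluster relative frequencies of fuzzy codes F1..F5 over non-null cells.

    ``patterns`` is the (n, L) array of category codes aligned with ``labels``;
    code 0 (absent) is excluded from the denominators.  Rows with no non-null
    codes report zero frequencies.
    """
    X = np.asarray(patterns, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("labels and patterns are not aligned")
    rows = []
    for c in np.unique(labels):
        member = X[labels == c]
        codes = member[member > 0]
        row = {"cluster": int(c), "n_patterns": int(member.shape[0]), "n_nonnull": int(codes.size)}
        freqs = np.bincount(codes, minlength=6)[1:6] / codes.size if codes.size else np.zeros(5)
        row.update({f"F{i + 1}": float(freqs[i]) for i in range(5)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


@dataclass(frozen=True)
class ContingencyTable:
    """Therapy x monitoring cluster tallies over monitored (day, hour) pairs."""

    counts: pd.DataFrame
    freq: pd.DataFrame
    grand_total: int


def contingency(stay_table: pd.DataFrame) -> ContingencyTable:
    """Tally (therapy cluster, monitoring cluster) pairs over monitored hours.

    Hourly cells of 0 (no monitoring) are excluded; ``freq`` cells are
    fractions of the grand total, so the whole table sums to 1.
    """
    if stay_table.shape[0] == 0:
        raise ValueError("empty stay table")
    long = stay_table.melt(
        id_vars=["therapy_cluster"],
        value_vars=list(HOUR_COLUMNS),
        value_name="cell",
    )
    long = long[long["cell"] > 0]
    if long.shape[0] == 0:
        raise ValueError("stay table has no monitored hours")
    long["monitoring_cluster"] = long["cell"] - 1
    counts = pd.crosstab(long["therapy_cluster"], long["monitoring_cluster"])
    grand = int(counts.to_numpy().sum())
    return ContingencyTable(counts=counts, freq=counts / grand, grand_total=grand)


def chi_square(counts) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a table of raw counts.

    Returns (statistic, dof, p) with dof = (r-1)(c-1); no continuity
    correction.  A zero row or column marginal raises.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a 2-D table with at least 2 rows and 2 columns")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal")
    res = sps.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass(frozen=True)
class NabtclSummary:
    """Population tables stratified by Nabtcl (distinct therapy clusters per stay).

    ``therapy_mix``/``monitoring_mix``/``duration_mix`` columns are the strata
    ("Nabtcl 1", ...) and each column sums to 1 over its clusters/subsets.
    """

    nabtcl: pd.Series
    stay_counts: pd.Series
    hour_counts: pd.Series
    therapy_mix: pd.DataFrame
    monitoring_mix: pd.DataFrame
    duration_mix: pd.DataFrame | None = None


def nabtcl_summary(stay_table: pd.DataFrame, overall_codes: pd.DataFrame | None = None) -> NabtclSummary:
    """Stratify the population by the number of distinct therapy clusters per stay.

    ``overall_codes`` (optional): patient_id, date, code — the fuzzified
    overall-days category of each patient-day, yielding the duration-by-stratum
    distribution (codes 0 excluded).
    """
    if stay_table.shape[0] == 0:
        raise ValueError("empty stay table")
    df = stay_table.copy()
    nabtcl = df.groupby("patient_id")["therapy_cluster"].nunique().rename("nabtcl")
    df = df.merge(nabtcl, on="patient_id")
    strata = sorted(nabtcl.unique())
    names = {s: f"Nabtcl {s}" for s in strata}

    stay_counts = nabtcl.value_counts().sort_index().rename(index=names)
    hours = (df[list(HOUR_COLUMNS)] > 0).sum(axis=1)
    hour_counts = hours.groupby(df["nabtcl"]).sum().rename(index=names)

    therapy_mix = (
        pd.crosstab(df["therapy_cluster"], df["nabtcl"], normalize="columns").rename(columns=names)
    )

    long = df.melt(id_vars=["nabtcl"], value_vars=list(HOUR_COLUMNS), value_name="cell")
    long = long[long["cell"] > 0]
    long["monitoring_cluster"] = long["cell"] - 1
    monitoring_mix = (
        pd.crosstab(long["monitoring_cluster"], long["nabtcl"], normalize="columns").rename(columns=names)
    )

    duration_mix = None
    if overall_codes is not None:
        oc = overall_codes.copy()
        oc["date"] = pd.to_datetime(oc["date"]).dt.normalize()
        oc = oc.merge(df[["patient_id", "date", "nabtcl"]], on=["patient_id", "date"])
        oc = oc[oc["code"] > 0]
        duration_mix = (
            pd.crosstab(oc["code"], oc["nabtcl"], normalize="columns").rename(columns=names)
        )
        duration_mix.index = [f"F{c}" for c in duration_mix.index]

    return NabtclSummary(
        nabtcl=nabtcl,
        stay_counts=stay_counts,
        hour_counts=hour_counts,
        therapy_mix=therapy_mix,
        monitoring_mix=monitoring_mix,
        duration_mix=duration_mix,
    )


def extract_stay_window(stay_table: pd.DataFrame, patient_id, n_hours: int = 14) -> pd.DataFrame:
    """First ``n_hours`` monitored hours of one patient's stay, for charting.

    Returns columns hour_index, therapy_cluster, monitoring_cluster in
    chronological order.  Unknown patient raises.
    """
    rows = stay_table[stay_table["patient_id"] == patient_id]
    if rows.shape[0] == 0:
        raise ValueError(f"unknown patient {patient_id!r}")
    records = []
    for _, row in rows.sort_values("date").iterrows():
        for h, col in enumerate(HOUR_COLUMNS):
            if row[col] > 0:
                records.append(
                    {
                        "hour_index": len(records),
                        "therapy_cluster": int(row["therapy_cluster"]),
                        "monitoring_cluster": int(row[col]) - 1,
                    }
                )
            if len(records) >= n_hours:
                break
        if len(records) >= n_hours:
            break
    return pd.DataFrame(records, columns=["hour_index", "therapy_cluster", "monitoring_cluster"])


def stay_chart(window: pd.DataFrame, path=None):
    """Paired therapy/monitoring cluster bars per hour for one patient window.

    ``window`` is the output of :func:`extract_stay_window`; bar heights equal
    cluster ids.  Empty window raises.
    """
    if window.shape[0] == 0:
        raise ValueError("empty window")
    import matplotlib.pyplot as plt

    x = np.asarray(window["hour_index"], dtype=float)
    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.bar(x - 0.2, window["therapy_cluster"], width=0.4, color="tab:blue", label="therapy cluster")
    ax.bar(x + 0.2, window["monitoring_cluster"], width=0.4, color="tab:red", label="monitoring cluster")
    ax.set_xlabel("monitored hour")
    ax.set_ylabel("cluster id")
    ax.set_xticks(x)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig


def plot_fuzzified_ribbon(codes: pd.DataFrame, path=None):
    """Ribbon view of fuzzified parameters over time for one patient.

    ``codes``: rows = consecutive hours, columns = parameters, values =
    category codes 0..5.  Each parameter is drawn as a filled ribbon whose
    height is the normalized category, stacked vertically.
    """
    if codes.shape[0] == 0 or codes.shape[1] == 0:
        raise ValueError("empty window")
    import matplotlib.pyplot as plt

    hours = np.arange(codes.shape[0])
    fig, ax = plt.subplots(figsize=(9, max(3.0, 0.45 * codes.shape[1])))
    for i, col in enumerate(codes.columns):
        base = i * 6.0
        vals = codes[col].to_numpy(dtype=float)
        ax.fill_between(hours, base, base + vals, step="mid", alpha=0.7)
        ax.text(-0.6, base + 2.5, str(col), ha="right", va="center", fontsize=7)
    ax.set_xlabel("hour")
    ax.set_yticks([])
    ax.set_xlim(-0.5, codes.shape[0] - 0.5)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig
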