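"""qPCR relative expression by the 2^-ddCt method.

Per replicate, dCt = Ct(target) - Ct(endogenous control, U6 role); ddCt
subtracts the calibrator miRNA's mean dCt, and fold change is 2^-ddCt, so
the calibrator's mean fold change is 1 by construction. Replicate folds
are summarized per miRNA (mean, sd, log10) and compared by one-way ANOVA
with Tukey HSD all-pairs testing; compact letter display groups miRNAs
that are not significantly different.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("mirna", "replicate", "ct_target", "ct_reference")


def _validate(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing column(s) {missing}")
    bad = ct[ct[["ct_target", "ct_reference"]].isna().any(axis=1)]
    if len(bad):
        rows = [f"{r.mirna}/{r.replicate}" for r in bad.itertuples()]
        raise ValueError(f"missing Ct value(s) for record(s): {', '.join(rows)}")
    out_of_range = ct[
        (ct["ct_target"] <= 0) | (ct["ct_target"] >= 45)
        | (ct["ct_reference"] <= 0) | (ct["ct_reference"] >= 45)
    ]
    if len(out_of_range):
        raise ValueError("Ct values must lie strictly between 0 and 45 cycles")
    return ct


def ddct(ct: pd.DataFrame, calibrator: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative expression via 2^-ddCt.

    ``ct`` needs columns mirna, replicate, ct_target, ct_reference (one row
    per replicate). Returns ``(per_replicate, summary)``: the replicate
    table carries delta_ct, delta_delta_ct, fold_change and log10_fold per
    row; the summary has one row per miRNA with mean fold, sd across
    replicate folds, mean log10 fold, and delta-Ct means. The result is
    invariant to replicate ordering and to any constant shift of the
    reference channel.
    """
    ct = _validate(ct.copy())
    if calibrator not in set(ct["mirna"]):
        raise ValueError(f"calibrator {calibrator!r} absent from Ct table")
    ct["delta_ct"] = ct["ct_target"] - ct["ct_reference"]
    cal_mean = ct.loc[ct["mirna"] == calibrator, "delta_ct"].mean()
    ct["delta_delta_ct"] = ct["delta_ct"] - cal_mean
    ct["fold_change"] = np.power(2.0, -ct["delta_delta_ct"])
    ct["log10_fold"] = np.log10(ct["fold_change"])
    summary = (
        ct.groupby("mirna", sort=False)
        .agg(
            n_replicates=("replicate", "nunique"),
            mean_delta_ct=("delta_ct", "mean"),
            mean_delta_delta_ct=("delta_delta_ct", "mean"),
            mean_fold=("fold_change", "mean"),
            sd_fold=("fold_change", "std"),
            mean_log10_fold=("log10_fold", "mean"),
            sd_log10_fold=("log10_fold", "std"),
        )
        .reset_index()
    )
    # geometric-mean fold: 2^-(mean ddCt); exactly 1 for the calibrator
    summary["gm_fold"] = np.power(2.0, -summary["mean_delta_delta_ct"])
    return ct, summary


def average_technical(ct: pd.DataFrame, pattern: str = r"^(b\d+)") -> pd.DataFrame:
    """Average technical replicates within each biological replicate.

    Replicate ids matching ``pattern`` (default ``b<k>t<j>``) collapse to
    their biological group mean on both Ct channels, implementing the
    two-layer (biological x technical) replicate structure; ids that do not
    match are left as their own group.
    """
    ct = ct.copy()
    ct["_bio"] = ct["replicate"].astype(str).str.extract(pattern, expand=False)
    ct["_bio"] = ct["_bio"].fillna(ct["replicate"].astype(str))
    out = (
        ct.groupby(["mirna", "_bio"], sort=False)[["ct_target", "ct_reference"]]
        .mean()
        .reset_index()
        .rename(columns={"_bio": "replicate"})
    )
    return out


def _compact_letters(
    names: list[str], means: dict[str, float], distinct: set[frozenset]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``distinct`` holds unordered pairs that differ significantly; names are
    processed (and letters ordered) by descending mean.
    """
    order = sorted(names, key=lambda n: -means[n])
    groups: list[set[str]] = []  # each group: names sharing one letter
    for name in order:
        placed = False
        for grp in groups:
            if all(frozenset((name, other)) not in distinct for other in grp):
                grp.add(name)
                placed = True
        if not placed:
            groups.append({name})
    # absorb groups fully contained in another
    groups = [
        g for i, g in enumerate(groups)
        if not any(i != j and g < other for j, other in enumerate(groups))
    ]
    letters: dict[str, str] = {n: "" for n in names}
    for i, grp in enumerate(groups):
        letter = chr(ord("a") + i)
        for name in order:
            if name in grp:
                letters[name] += letter
    return letters


def letter_groups(
    per_replicate: pd.DataFrame,
    alpha: float = 0.05,
    value_column: str = "log10_fold",
) -> pd.DataFrame:
    """Compact-letter grouping of miRNAs from replicate-level fold values.

    One-way ANOVA across miRNAs on ``value_column``; when significant at
    ``alpha``, all-pairs Tukey HSD decides which pairs differ and letters
    are assigned so that miRNAs sharing a letter are not significantly
    different. miRNAs with fewer than two replicates are excluded with a
    warning; a lone miRNA (or a non-significant ANOVA) yields letter 'a'
    for everyone.
    """
    counts = per_replicate.groupby("mirna")[value_column].count()
    few = counts[counts < 2].index.tolist()
    if few:
        warnings.warn(f"excluded miRNA(s) with < 2 replicates: {few}", stacklevel=2)
    data = per_replicate[~per_replicate["mirna"].isin(few)]
    names = list(dict.fromkeys(data["mirna"]))
    means = data.groupby("mirna")[value_column].mean().to_dict()
    if len(names) <= 1:
        letters = {n: "a" for n in names}
    else:
        samples = [data.loc[data["mirna"] == n, value_column].to_numpy() for n in names]
        _, p_anova = stats.f_oneway(*samples)
        distinct: set[frozenset] = set()
        if p_anova < alpha:
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            tuk = pairwise_tukeyhsd(
                data[value_column].to_numpy(), data["mirna"].to_numpy(), alpha=alpha
            )
            res = pd.DataFrame(
                tuk.summary().data[1:], columns=tuk.summary().data[0]
            )
            for row in res.itertuples():
                if bool(row.reject):
                    distinct.add(frozenset((row.group1, row.group2)))
        letters = _compact_letters(names, means, distinct)
    out = pd.DataFrame(
        {
            "mirna": names,
            "mean_value": [means[n] for n in names],
            "group_letter": [letters[n] for n in names],
        }
    ).sort_values("mean_value", ascending=False).reset_index(drop=True)
    return out


def plot_expression(summary: pd.DataFrame, letters: pd.DataFrame, path) -> None:
    """Bar plot of log10 relative expression with sd error bars and letters."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    merged = summary
    if "group_letter" not in merged.columns:
        merged = merged.merge(letters[["mirna", "group_letter"]], on="mirna", how="left")
    fig, ax = plt.subplots(figsize=(1.2 * len(merged) + 1, 4))
    sd = merged["sd_log10_fold"].fillna(0.0)
    ax.bar(merged["mirna"], merged["mean_log10_fold"], yerr=sd, capsize=3, color="#4878a8")
    for x, (y, s, letter) in enumerate(
        zip(merged["mean_log10_fold"], sd, merged["group_letter"].fillna(""))
    ):
        ax.text(x, y + s + 0.05, letter, ha="center")
    ax.axhline(0, color="black", lw=0.8)
    ax.set_ylabel("relative expression (log10 fold)")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def make_synthetic_ct(
    true_folds: dict[str, float],
    calibrator: str,
    seed: int,
    n_biological: int = 2,
    n_technical: int = 3,
    noise_sd: float = 0.1,
    reference_ct: float = 20.0,
    calibrator_delta_ct: float = 5.0,
) -> pd.DataFrame:
    """Simulate a Ct table from known fold changes with Gaussian Ct noise.

    Each miRNA's true dCt is calibrator dCt - log2(fold); biological x
    technical replicates get independent N(0, noise_sd) cycles of noise on
    the target channel. The calibrator must be in ``true_folds`` with fold
    1.0. Used for parameter-recovery testing of :func:`ddct`.
    """
    if calibrator not in true_folds:
        raise ValueError("calibrator must be included in true_folds")
    rng = np.random.default_rng(seed)
    rows = []
    for mirna, fold in true_folds.items():
        if fold <= 0:
            raise ValueError("fold changes must be positive")
        d_ct = calibrator_delta_ct - np.log2(fold)
        for b in range(n_biological):
            for t in range(n_technical):
                rows.append(
                    {
                        "mirna": mirna,
                        "replicate": f"b{b + 1}t{t + 1}",
                        "ct_target": reference_ct + d_ct + rng.normal(0.0, noise_sd),
                        "ct_reference": reference_ct,
                    }
                )
    return pd.DataFrame(rows)
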