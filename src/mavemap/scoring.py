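"""Enrichment scoring of pre/post-selection variant counts.

Implements the standard multiplexed-assay scoring chain for tiled amplicon
sequencing data:

1. counts -> variant allele frequencies (and counts per million);
2. per-replicate quality filters (raw-count floor, within-tile wild-type
   control percentile, well-measured frequency floor);
3. wild-type-control error correction and enrichment ratios
   phi = f'_post / f'_pre on corrected frequencies, worked in log2;
4. replicate-agreement-based standard-error regularization;
5. inverse-variance replicate averaging with Welch–Satterthwaite degrees
   of freedom;
6. rescaling so the nonsense median maps to 0 and the synonymous median
   to 1.

All functions take and return long-format :class:`pandas.DataFrame` objects
keyed by ``hgvs_p``; the input schema matches the count tables written by
:mod:`mavemap.synthetic` (and any real data in the same format).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .variants import VariantClass

#: excluding quality flags (``single_replicate`` is informational only)
FILTER_FLAGS = ("low_count", "below_wt_p90", "not_well_measured")
ALL_FLAGS = FILTER_FLAGS + ("nonpositive_corrected_pre", "single_replicate")

RAW_COUNT_MIN = 10  # pre-selection reads
CPM_MIN = 10.0  # pre-selection counts per million ("well-measured")
WT_PERCENTILE = 90.0  # within-tile WT-control frequency percentile

_KEY = ["hgvs_p", "condition", "replicate", "tile"]


def compute_frequencies(counts: pd.DataFrame) -> pd.DataFrame:
    """Add ``freq`` (reads/read) and ``cpm`` columns to a count table."""
    if (counts["depth"] <= 0).any():
        bad = counts.loc[counts["depth"] <= 0, _KEY].iloc[0].to_dict()
        raise ValueError(f"non-positive depth in count table at {bad}")
    dup = counts.duplicated(subset=_KEY)
    if dup.any():
        raise ValueError(
            f"duplicate count rows for {counts.loc[dup, _KEY].iloc[0].to_dict()}"
        )
    out = counts.copy()
    out["freq"] = out["count"] / out["depth"]
    out["cpm"] = 1e6 * out["freq"]
    return out


def _variant_rows(freqs: pd.DataFrame) -> pd.DataFrame:
    return freqs[freqs["vclass"] != "wt"]


def apply_filters(freqs: pd.DataFrame, wt_freqs: pd.DataFrame) -> pd.DataFrame:
    """Per-(variant, replicate) quality flags from pre-selection data.

    Flags: ``low_count`` (pre-selection reads < 10), ``below_wt_p90``
    (pre-selection frequency at or below the 90th percentile of the
    WT-control frequency distribution over variants within the same tile),
    ``not_well_measured`` (pre-selection cpm < 10).  A variant is excluded
    downstream only when it carries at least one flag in every replicate.
    """
    wt_pre = _variant_rows(wt_freqs[wt_freqs["condition"] == "wt_pre"])
    if wt_pre.empty:
        raise ValueError("empty WT-control table: cannot compute error percentiles")
    p90 = (
        wt_pre.groupby(["tile", "replicate"])["freq"]
        .quantile(WT_PERCENTILE / 100.0)
        .rename("wt_p90")
    )

    pre = _variant_rows(freqs[freqs["condition"] == "pre"]).copy()
    pre = pre.join(p90, on=["tile", "replicate"])
    pre["low_count"] = pre["count"] < RAW_COUNT_MIN
    pre["below_wt_p90"] = pre["freq"] <= pre["wt_p90"]
    pre["not_well_measured"] = pre["cpm"] < CPM_MIN
    cols = ["hgvs_p", "replicate", "tile", "low_count", "below_wt_p90", "not_well_measured"]
    return pre[cols].reset_index(drop=True)


def correct_and_enrich(freqs: pd.DataFrame, wt_freqs: pd.DataFrame) -> pd.DataFrame:
    """WT-error-corrected enrichment ratios per variant and replicate.

    Corrected frequencies are f' = f(library) - f(WT control) per condition;
    phi = f'_post / f'_pre.  A non-positive corrected pre-selection
    frequency makes the ratio meaningless (``nonpositive_corrected_pre``);
    a non-positive corrected post-selection frequency is floored at one
    pseudo-read (1/depth) so fully depleted variants stay scoreable.
    """
    lib = _variant_rows(freqs)
    wt = _variant_rows(wt_freqs)
    pre = lib[lib["condition"] == "pre"]
    post = lib[lib["condition"] == "post"]
    wt_pre = wt[wt["condition"] == "wt_pre"]
    wt_post = wt[wt["condition"] == "wt_post"]

    keys = ["hgvs_p", "replicate"]
    merged = (
        pre.rename(columns={"freq": "f_pre", "cpm": "cpm_pre", "count": "count_pre"})[
            ["hgvs_p", "replicate", "tile", "position", "from_aa", "to_aa", "vclass",
             "f_pre", "cpm_pre", "count_pre", "depth"]
        ]
        .merge(
            post.rename(columns={"freq": "f_post"})[keys + ["f_post"]],
            on=keys, how="left",
        )
        .merge(
            wt_pre.rename(columns={"freq": "f_wt_pre"})[keys + ["f_wt_pre"]],
            on=keys, how="left",
        )
        .merge(
            wt_post.rename(columns={"freq": "f_wt_post"})[keys + ["f_wt_post"]],
            on=keys, how="left",
        )
    )
    missing = merged["f_wt_pre"].isna() | merged["f_wt_post"].isna()
    if missing.any():
        name = merged.loc[missing, "hgvs_p"].iloc[0]
        raise ValueError(f"no matched WT-control row for variant {name}")
    merged["f_post"] = merged["f_post"].fillna(0.0)

    fp_pre = merged["f_pre"] - merged["f_wt_pre"]
    fp_post = merged["f_post"] - merged["f_wt_post"]
    fp_post = fp_post.where(fp_post > 0, 1.0 / merged["depth"])

    merged["nonpositive_corrected_pre"] = fp_pre <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(fp_pre > 0, fp_post / fp_pre, np.nan)
    merged["phi"] = phi
    merged["log_phi"] = np.log2(phi)
    return merged


def regularize_errors(enrich: pd.DataFrame, m: float = 2.0) -> pd.DataFrame:
    """Regularize per-replicate log-ratio standard errors.

    The empirical sd of ``log_phi`` across replicates is noisy for any one
    variant, but its trend against pre-selection frequency is stable: fit
    ``log(sd_emp) ~ log(cpm_pre)`` over variants with replicate pairs, then
    shrink each variant's empirical sd toward the model prediction with
    pseudo-observation weight ``m``:

        se_reg^2 = (m * sd_model^2 + (n - 1) * sd_emp^2) / (m + n - 1)

    with ``n`` the replicate count and ``df = m + n - 1``.
    """
    if m < 0:
        raise ValueError("pseudo-observation weight m must be >= 0")
    df = enrich[~enrich["nonpositive_corrected_pre"] & enrich["log_phi"].notna()].copy()
    grp = df.groupby("hgvs_p")["log_phi"]
    sd_emp = grp.std(ddof=1).rename("sd_emp")
    n_rep = grp.size().rename("n_rep")
    df = df.join(sd_emp, on="hgvs_p").join(n_rep, on="hgvs_p")

    fit_mask = (df["n_rep"] >= 2) & (df["sd_emp"] > 0) & (df["cpm_pre"] > 0)
    n_pairs = df.loc[fit_mask, "hgvs_p"].nunique()
    if n_pairs < 30:
        raise ValueError(
            f"only {n_pairs} variants with replicate pairs; need >= 30 "
            "for the error model (simulate more data)"
        )
    x = np.log(df.loc[fit_mask, "cpm_pre"].to_numpy())
    y = np.log(df.loc[fit_mask, "sd_emp"].to_numpy())
    slope, intercept = np.polyfit(x, y, 1)

    with np.errstate(divide="ignore"):
        logc = np.log(df["cpm_pre"].to_numpy())
    df["sd_model"] = np.exp(slope * logc + intercept)
    sd_e = df["sd_emp"].fillna(0.0).to_numpy()
    n = df["n_rep"].to_numpy()
    if m == 0:
        df["se_reg"] = sd_e
        df["df"] = n - 1
    else:
        df["se_reg"] = np.sqrt(
            (m * df["sd_model"] ** 2 + (n - 1) * sd_e**2) / (m + n - 1)
        )
        df["df"] = m + n - 1
    df.attrs["error_model"] = {"slope": float(slope), "intercept": float(intercept)}
    return df


def combine_replicates(enrich: pd.DataFrame) -> pd.DataFrame:
    """Inverse-variance weighted replicate average of ``log_phi``.

    Weights are 1/se_reg^2; the combined se is sqrt(1/sum(w)) and degrees
    of freedom follow Welch–Satterthwaite.  Variants observed in a single
    replicate pass through unchanged with a ``single_replicate`` flag.
    """
    rows = []
    for hgvs, g in enrich.groupby("hgvs_p", sort=False):
        w = 1.0 / g["se_reg"].to_numpy() ** 2
        x = g["log_phi"].to_numpy()
        dfs = g["df"].to_numpy(dtype=float)
        meta = g.iloc[0]
        if len(g) == 1:
            rows.append(
                dict(hgvs_p=hgvs, position=meta["position"], from_aa=meta["from_aa"],
                     to_aa=meta["to_aa"], vclass=meta["vclass"], tile=meta["tile"],
                     log_phi=float(x[0]), se=float(g["se_reg"].iloc[0]),
                     df=float(dfs[0]), single_replicate=True)
            )
            continue
        sw = w.sum()
        mean = float((w * x).sum() / sw)
        se = float(np.sqrt(1.0 / sw))
        nu = float(sw**2 / (w**2 / dfs).sum())
        rows.append(
            dict(hgvs_p=hgvs, position=meta["position"], from_aa=meta["from_aa"],
                 to_aa=meta["to_aa"], vclass=meta["vclass"], tile=meta["tile"],
                 log_phi=mean, se=se, df=nu, single_replicate=False)
        )
    return pd.DataFrame(rows)


def rescale_scores(combined: pd.DataFrame) -> pd.DataFrame:
    """Map combined enrichment ratios onto the nonsense=0 / synonymous=1 scale.

    Replicate noise is handled in log2 space (where it is symmetric), but
    the final score lives on the linear ratio scale:

        score = (phi - median_nonsense_phi) / (median_syn_phi - median_nonsense_phi)

    with phi = 2**log_phi and the standard error mapped through the delta
    method (se_phi = phi * ln 2 * se_log).  Anchor medians are taken on the
    linear phi scale, so nonsense and synonymous medians map to exactly 0
    and 1.
    """
    non = combined.loc[combined["vclass"] == VariantClass.nonsense.value, "log_phi"]
    syn = combined.loc[combined["vclass"] == VariantClass.synonymous.value, "log_phi"]
    if len(non) < 10 or len(syn) < 10:
        raise ValueError(
            f"need >= 10 scored nonsense and synonymous variants for rescaling "
            f"(have {len(non)} / {len(syn)})"
        )
    phi = np.exp2(combined["log_phi"])
    med_non = float(np.median(np.exp2(non)))
    med_syn = float(np.median(np.exp2(syn)))
    if med_syn <= med_non:
        raise ValueError(
            f"synonymous median ratio ({med_syn:.3g}) <= nonsense median "
            f"({med_non:.3g}): selection failed or inverted"
        )
    span = med_syn - med_non
    out = combined.copy()
    out["score"] = (phi - med_non) / span
    out["se"] = phi * np.log(2.0) * out["se"] / span
    out.attrs["rescale"] = {"median_nonsense": med_non, "median_synonymous": med_syn}
    return out


def score_counts(
    lib_counts: pd.DataFrame, wt_counts: pd.DataFrame, m: float = 2.0
) -> pd.DataFrame:
    """Full scoring chain from count tables to rescaled scores.

    Returns one row per variant.  Excluded variants (flagged in every
    replicate, or unscoreable) are retained with NaN score and their flags
    recorded in a comma-separated ``flags`` column.
    """
    freqs = compute_frequencies(lib_counts)
    wt_freqs = compute_frequencies(wt_counts)
    flags = apply_filters(freqs, wt_freqs)
    enrich = correct_and_enrich(freqs, wt_freqs)

    enrich = enrich.merge(flags, on=["hgvs_p", "replicate", "tile"], how="left")
    for f in FILTER_FLAGS:
        enrich[f] = enrich[f].fillna(False)
    enrich["any_filter"] = enrich[list(FILTER_FLAGS)].any(axis=1)

    # a replicate contributes only if it passes the filters and has a ratio
    usable = enrich[~enrich["any_filter"] & ~enrich["nonpositive_corrected_pre"]]

    n_rep_total = enrich.groupby("hgvs_p")["replicate"].nunique()

    excluded_rows = []
    for hgvs, g in enrich.groupby("hgvs_p", sort=False):
        if hgvs in set(usable["hgvs_p"]):
            continue
        fl = [f for f in FILTER_FLAGS if g[f].all()]
        if g["nonpositive_corrected_pre"].all():
            fl.append("nonpositive_corrected_pre")
        if not fl:  # mixed causes across replicates
            fl = sorted(
                {f for f in FILTER_FLAGS + ("nonpositive_corrected_pre",) if g[f].any()}
            )
        meta = g.iloc[0]
        excluded_rows.append(
            dict(hgvs_p=hgvs, position=meta["position"], from_aa=meta["from_aa"],
                 to_aa=meta["to_aa"], vclass=meta["vclass"], tile=meta["tile"],
                 score=np.nan, se=np.nan, df=np.nan, flags=",".join(fl))
        )

    reg = regularize_errors(usable, m=m)
    combined = combine_replicates(reg)
    scored = rescale_scores(combined)
    scored["flags"] = np.where(scored["single_replicate"], "single_replicate", "")
    scored = scored.drop(columns=["single_replicate", "log_phi"])

    out = pd.concat([scored, pd.DataFrame(excluded_rows)], ignore_index=True)
    out = out.sort_values(["position", "to_aa"]).reset_index(drop=True)
    out.attrs.update(scored.attrs)
    out.attrs["error_model"] = reg.attrs.get("error_model")
    out.attrs["n_replicates"] = int(n_rep_total.max()) if len(n_rep_total) else 0
    return out


def write_scores(scores: pd.DataFrame, out_dir: str | Path) -> None:
    """Write the score TSV plus a MaveDB-style CSV (hgvs_pro, score, se)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = ["hgvs_p", "position", "from_aa", "to_aa", "vclass", "score", "se", "df", "flags"]
    scores[cols].to_csv(out / "scores.tsv", sep="\t", index=False)
    mave = scores.loc[scores["score"].notna(), ["hgvs_p", "score", "se"]].rename(
        columns={"hgvs_p": "hgvs_pro"}
    )
    mave.to_csv(out / "scores_mavedb.csv", index=False)
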