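"""Effect-map assembly and map-level statistical analyses.

Arranges per-variant scores into a position x residue matrix, classifies
cells as damaging / tolerated / hyperactive, finds the data-driven
damaging threshold at the density minimum between the two modes of the
missense score distribution, and runs the standard map-level analyses:
amino-acid deleteriousness vectors, residue-property group contrasts,
population counter-selection, stability (ddG) discordance, and phenotype
correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .variants import STOP, VariantClass

AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY") + (STOP,)

#: amino-acid property groups used by the built-in contrasts
HYDROPHOBIC = set("AVLIMFWC")
POLAR_UNCHARGED = set("STNQYGP")
CHARGED = set("DEKRH")
NEGATIVE = set("DE")

#: substitutions considered conservative (within-group, BLOSUM-style)
CONSERVATIVE_GROUPS = (
    set("AVLIM"), set("FWY"), set("ST"), set("NQ"), set("DE"), set("KR"), set("C"),
    set("G"), set("P"), set("H"),
)

DEFAULT_DAMAGING_THRESHOLD = {"activity": 0.5, "abundance": -0.4}


@dataclass
class EffectMap:
    """Position x residue score matrix with per-cell classes.

    ``scores``/``se`` are (L x 21) DataFrames indexed by position with one
    column per residue (stop last); ``classes`` holds one of
    {damaging, tolerated, hyper, missing, wt} per cell.
    """

    scores: pd.DataFrame
    se: pd.DataFrame
    classes: pd.DataFrame
    wt_sequence: str
    damaging_threshold: float
    consensus: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        L = len(self.wt_sequence)
        if self.scores.shape != (L, len(AA_ORDER)):
            raise ValueError(
                f"score matrix shape {self.scores.shape} != ({L}, {len(AA_ORDER)})"
            )
        cons = {}
        for pos in self.scores.index:
            wt = self.wt_sequence[pos - 1]
            row = self.scores.loc[pos].drop([wt, STOP], errors="ignore")
            cons[pos] = float(np.nanmedian(row)) if row.notna().any() else np.nan
        self.consensus = pd.Series(cons, name="consensus")

    @property
    def L(self) -> int:
        return len(self.wt_sequence)

    def long_frame(self) -> pd.DataFrame:
        """Long-format view: one row per (position, to_aa) cell."""
        rows = []
        for pos in self.scores.index:
            for aa in AA_ORDER:
                rows.append(
                    dict(position=pos, from_aa=self.wt_sequence[pos - 1], to_aa=aa,
                         score=self.scores.at[pos, aa], se=self.se.at[pos, aa],
                         cell_class=self.classes.at[pos, aa])
                )
        return pd.DataFrame(rows)

    def missense_scores(self) -> pd.DataFrame:
        lf = self.long_frame()
        mis = lf[(lf["to_aa"] != STOP) & (lf["to_aa"] != lf["from_aa"])]
        return mis[mis["score"].notna()]


def build_effect_map(
    scores: pd.DataFrame,
    wt_sequence: str,
    damaging_threshold: float = 0.5,
) -> EffectMap:
    """Assemble an :class:`EffectMap` from a per-variant score table.

    Cells are damaging when score < ``damaging_threshold``, hyperactive
    when score > 1 + 2*se, otherwise tolerated; cells without a score are
    missing and wild-type identity cells carry no score.
    """
    L = len(wt_sequence)
    idx = pd.RangeIndex(1, L + 1, name="position")
    mat = pd.DataFrame(np.nan, index=idx, columns=list(AA_ORDER))
    se_mat = mat.copy()
    classes = pd.DataFrame("missing", index=idx, columns=list(AA_ORDER))

    scored = scores[scores["score"].notna()]
    for row in scored.itertuples():
        pos = int(row.position)
        if not 1 <= pos <= L:
            raise ValueError(f"variant {row.hgvs_p} position {pos} outside 1..{L}")
        if row.from_aa != wt_sequence[pos - 1]:
            raise ValueError(
                f"numbering mismatch: {row.hgvs_p} has from_aa {row.from_aa} but "
                f"wt_sequence[{pos}] is {wt_sequence[pos - 1]}"
            )
        if row.to_aa == row.from_aa:
            continue  # wt cell carries no score
        mat.at[pos, row.to_aa] = row.score
        se_mat.at[pos, row.to_aa] = row.se
        if row.score < damaging_threshold:
            cls = "damaging"
        elif np.isfinite(row.se) and row.score > 1.0 + 2.0 * row.se:
            cls = "hyper"
        else:
            cls = "tolerated"
        classes.at[pos, row.to_aa] = cls

    for pos in idx:
        classes.at[pos, wt_sequence[pos - 1]] = "wt"

    return EffectMap(mat, se_mat, classes, wt_sequence, damaging_threshold)


def find_bimodal_threshold(
    missense_scores: np.ndarray | pd.Series,
    fallback: float = 0.5,
    min_n: int = 100,
    grid_size: int = 2048,
) -> float:
    """Damaging-score cutoff at the density minimum between the two modes.

    A Gaussian KDE is evaluated on a fine grid; the threshold is the
    location of minimum density between the two highest local maxima.  If
    the estimate is unimodal the configured ``fallback`` is returned with
    a warning.
    """
    x = np.asarray(missense_scores, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < min_n:
        raise ValueError(f"need >= {min_n} missense scores, got {len(x)}")
    kde = stats.gaussian_kde(x)
    lo, hi = x.min(), x.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)

    interior = np.arange(1, grid_size - 1)
    is_max = (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    peaks = interior[is_max]
    if len(peaks) < 2:
        warnings.warn(
            "missense score distribution looks unimodal; "
            f"falling back to the configured threshold {fallback}",
            stacklevel=2,
        )
        return fallback
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    left, right = sorted(top2)
    valley = left + int(np.argmin(dens[left : right + 1]))
    return float(grid[valley])


def _spearman(a, b) -> tuple[float | None, float | None]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return None, None  # undefined for constant input
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def deleteriousness_vectors(
    emap: EffectMap, reference_to: pd.Series | None = None,
    reference_from: pd.Series | None = None,
) -> dict:
    """Median score per target ('to') and per origin ('from') residue.

    Summarizes how damaging substitutions to, and from, each amino acid
    tend to be across the whole map; optionally correlates each vector
    (Spearman) with a user-supplied reference vector on the same residues.
    """
    mis = emap.missense_scores()
    to_vec = mis.groupby("to_aa")["score"].median().reindex(list("ACDEFGHIKLMNPQRSTVWY"))
    from_vec = mis.groupby("from_aa")["score"].median().dropna()
    out = {"to": to_vec, "from": from_vec}
    if reference_to is not None:
        common = to_vec.dropna().index.intersection(reference_to.dropna().index)
        rho, p = _spearman(to_vec[common], reference_to[common])
        out["to_spearman"] = {"rho": rho, "p": p, "n": len(common)}
    if reference_from is not None:
        common = from_vec.index.intersection(reference_from.dropna().index)
        rho, p = _spearman(from_vec[common], reference_from[common])
        out["from_spearman"] = {"rho": rho, "p": p, "n": len(common)}
    return out


def compare_groups(contrasts: list[tuple[str, np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Mann–Whitney U for each contrast with BH adjustment across the family.

    Contrasts with fewer than 3 observations on either side are skipped
    (recorded with NaN statistics and a notice flag).
    """
    rows = []
    for label, a, b in contrasts:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        row = dict(label=label, n_a=len(a), n_b=len(b),
                   median_a=np.median(a) if len(a) else np.nan,
                   median_b=np.median(b) if len(b) else np.nan)
        if len(a) < 3 or len(b) < 3:
            row.update(delta_median=np.nan, U=np.nan, p=np.nan, skipped=True)
        else:
            # small groups: exact permutation null (ties handled correctly);
            # large groups: the usual tie-corrected normal approximation
            method = "auto"
            if len(a) <= 8 and len(b) <= 8:
                method = stats.PermutationMethod(n_resamples=np.inf)
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            row.update(delta_median=row["median_a"] - row["median_b"],
                       U=float(res.statistic), p=float(res.pvalue), skipped=False)
        rows.append(row)
    out = pd.DataFrame(rows)
    tested = out[~out["skipped"] & out["p"].notna()]
    out["p_adj"] = np.nan
    if len(tested):
        out.loc[tested.index, "p_adj"] = multipletests(tested["p"], method="fdr_bh")[1]
    return out


def builtin_property_contrasts(
    emap: EffectMap, structure_classes: pd.Series | None = None,
    metal_positions: set[int] | None = None,
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """The standard residue-property contrasts for a missense map.

    ``structure_classes`` maps position -> {core, surface, interface};
    ``metal_positions`` marks metal-coordinating residues.  Contrasts based
    on missing annotations are omitted.
    """
    mis = emap.missense_scores()
    wt_prop = mis["from_aa"]

    def scores(mask):
        return mis.loc[mask, "score"].to_numpy()

    hydro = wt_prop.isin(HYDROPHOBIC)
    pro = mis["to_aa"] == "P"
    neg = mis["to_aa"].isin(NEGATIVE)
    conservative = mis.apply(
        lambda r: any(r["from_aa"] in g and r["to_aa"] in g for g in CONSERVATIVE_GROUPS),
        axis=1,
    )
    uncharged_site = ~wt_prop.isin(CHARGED)

    contrasts = [
        ("hydrophobic_vs_other_positions", scores(hydro), scores(~hydro)),
        ("proline_vs_other_substitutions", scores(pro), scores(~pro)),
        ("negative_charge_vs_other_substitutions", scores(neg), scores(~neg)),
        ("conservative_vs_other_at_uncharged", scores(conservative & uncharged_site),
         scores(~conservative & uncharged_site)),
    ]
    if structure_classes is not None:
        sc = mis["position"].map(structure_classes)
        metal = mis["position"].isin(metal_positions or set())
        contrasts += [
            ("core_vs_surface", scores((sc == "core") & ~metal),
             scores((sc == "surface") & ~metal)),
            ("interface_vs_surface", scores((sc == "interface") & ~metal),
             scores((sc == "surface") & ~metal)),
        ]
        if metal_positions:
            contrasts.append(
                ("metal_binding_vs_surface", scores(metal), scores((sc == "surface") & ~metal))
            )
    return contrasts


def counter_selection_test(
    emap: EffectMap, observed_variants: list[str] | set[str]
) -> dict:
    """Are map-damaging substitutions depleted among observed variants?

    Builds the 2x2 table (damaging/tolerated x observed/unobserved) over
    scored missense cells and returns the natural-log odds ratio with
    Fisher's exact two-sided p-value.
    """
    mis = emap.missense_scores().copy()
    lf = emap.long_frame()
    cls = lf.set_index(["position", "to_aa"])["cell_class"]
    mis["damaging"] = [
        cls.at[(p, a)] == "damaging" for p, a in zip(mis["position"], mis["to_aa"])
    ]
    labels = {
        f"p.{_aa3(f)}{p}{_aa3(t)}"
        for p, f, t in zip(mis["position"], mis["from_aa"], mis["to_aa"])
    }
    observed = set(observed_variants) & labels
    if not observed:
        raise ValueError("observed variant list has no overlap with the map")
    mis["observed"] = [
        f"p.{_aa3(f)}{p}{_aa3(t)}" in observed
        for p, f, t in zip(mis["position"], mis["from_aa"], mis["to_aa"])
    ]
    a = int((mis["damaging"] & mis["observed"]).sum())
    b = int((mis["damaging"] & ~mis["observed"]).sum())
    c = int((~mis["damaging"] & mis["observed"]).sum())
    d = int((~mis["damaging"] & ~mis["observed"]).sum())
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"empty margin in contingency table {table.tolist()}")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    with np.errstate(divide="ignore"):
        log_or = float(np.log((a * d) / (b * c))) if b * c > 0 else np.inf
    return {"table": table, "log_odds_ratio": log_or, "p": float(p)}


def _aa3(aa: str) -> str:
    from Bio.SeqUtils import seq3

    return "Ter" if aa == STOP else seq3(aa)


def ddg_discordance(
    emap: EffectMap,
    ddg_table: pd.DataFrame,
    window: int = 10,
    step: int = 1,
    destabilizing_cutoff: float = -0.5,
    destabilizing_below: bool = True,
) -> dict:
    """Find positions whose functional loss is not explained by stability.

    Compares per-position median map score against per-position median
    predicted ddG.  A position is 'stable-but-inactive' when its median
    score is below the damaging threshold while its median ddG is on the
    non-destabilizing side of ``destabilizing_cutoff`` (by default ddG
    below the cutoff counts as destabilizing; set ``destabilizing_below``
    False for the opposite sign convention).  Also reports the overall
    Spearman correlation and sliding-window medians of both tracks.
    """
    mis = emap.missense_scores()
    score_med = mis.groupby("position")["score"].median()
    ddg_med = ddg_table.groupby("position")["ddg"].median()
    common = score_med.index.intersection(ddg_med.index)
    if len(common) == 0:
        raise ValueError("no position overlap between map and ddG table")
    s, g = score_med[common], ddg_med[common]
    rho, p = _spearman(s, g)
    if destabilizing_below:
        not_destab = g >= destabilizing_cutoff
    else:
        not_destab = g <= destabilizing_cutoff
    flags = (s < emap.damaging_threshold) & not_destab

    per_pos = pd.DataFrame(
        {"median_score": s, "median_ddg": g, "stable_but_inactive": flags}
    )
    win_rows = []
    pos = np.array(sorted(common))
    for start in range(0, max(len(pos) - window + 1, 1), step):
        block = pos[start : start + window]
        if len(block) == 0:
            break
        win_rows.append(
            dict(start=int(block[0]), end=int(block[-1]),
                 median_score=float(s[block].median()),
                 median_ddg=float(g[block].median()))
        )
    return {
        "per_position": per_pos,
        "windows": pd.DataFrame(win_rows),
        "spearman_rho": rho,
        "spearman_p": p,
    }


def collapse_studies(phenotype_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse multi-study phenotype rows to an n-weighted mean per
    (variant, phenotype)."""

    def wmean(g: pd.DataFrame) -> float:
        w = g["study_n"].to_numpy(dtype=float)
        v = g["value"].to_numpy(dtype=float)
        return float((w * v).sum() / w.sum())

    out = (
        phenotype_table.groupby(["hgvs_p", "phenotype"])
        .apply(wmean, include_groups=False)
        .rename("value")
        .reset_index()
    )
    return out


def phenotype_correlations(
    scores: pd.DataFrame, phenotype_table: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlation of map scores with each clinical phenotype.

    ``phenotype_table`` columns: hgvs_p, phenotype, value, study_n.
    Multi-study values are collapsed by sample-size-weighted mean first;
    p-values are BH-adjusted across the phenotype family.  Phenotypes with
    no scored variants are reported as skipped.
    """
    collapsed = collapse_studies(phenotype_table)
    merged = collapsed.merge(
        scores.loc[scores["score"].notna(), ["hgvs_p", "score"]], on="hgvs_p", how="left"
    )
    rows = []
    for name, g in merged.groupby("phenotype"):
        g = g[g["score"].notna() & g["value"].notna()]
        rho, p = _spearman(g["score"], g["value"]) if len(g) >= 3 else (None, None)
        rows.append(dict(phenotype=name, n=len(g), rho=rho, p=p,
                         skipped=rho is None))
    out = pd.DataFrame(rows)
    tested = out[~out["skipped"]]
    out["p_adj"] = np.nan
    if len(tested):
        out.loc[tested.index, "p_adj"] = multipletests(tested["p"], method="fdr_bh")[1]
    return out


def write_effect_map(emap: EffectMap, out_dir) -> None:
    """Export long TSV, matrix CSV, and per-position consensus TSV."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    emap.long_frame().to_csv(out / "effect_map_long.tsv", sep="\t", index=False)
    emap.scores.to_csv(out / "effect_map_matrix.csv")
    emap.consensus.rename_axis("position").to_csv(out / "consensus.tsv", sep="\t")
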