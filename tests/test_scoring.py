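"""Scoring chain: filters, enrichment, regularization, combination, rescaling.

The core check re-derives every score of a hand-built count fixture with an
independent, spreadsheet-style recomputation (plain Python arithmetic) and
requires agreement to 1e-9.
"""

import numpy as np
import pandas as pd
import pytest

from mavemap.scoring import (
    apply_filters,
    combine_replicates,
    compute_frequencies,
    correct_and_enrich,
    regularize_errors,
    rescale_scores,
    score_counts,
)


def _fixture_counts(n_var=45, depth=100_000, seed=21):
    """Two replicates, one tile, every variant passing the filters."""
    rng = np.random.default_rng(seed)
    rows_lib, rows_wt = [], []
    for i in range(n_var):
        if i < 12:
            vclass, frm, to = "nonsense", "A", "*"
        elif i < 24:
            vclass, frm, to = "synonymous", "L", "L"
        else:
            vclass, frm, to = "missense", "G", "R"
        hgvs = f"p.X{i + 1}{to}"
        scale = {"nonsense": 0.05, "synonymous": 1.0, "missense": 0.5}[vclass]
        for rep in (1, 2):
            pre = int(rng.integers(500, 3000))
            post = max(int(pre * scale * rng.uniform(0.8, 1.25)), 30)
            wt_pre, wt_post = int(rng.integers(0, 5)), int(rng.integers(0, 5))
            base = dict(replicate=rep, tile=1, hgvs_p=hgvs, position=i + 1,
                        from_aa=frm, to_aa=to, vclass=vclass, depth=depth)
            rows_lib.append({**base, "condition": "pre", "count": pre})
            rows_lib.append({**base, "condition": "post", "count": post})
            rows_wt.append({**base, "condition": "wt_pre", "count": wt_pre})
            rows_wt.append({**base, "condition": "wt_post", "count": wt_post})
    return pd.DataFrame(rows_lib), pd.DataFrame(rows_wt)


def _oracle_scores(lib, wt, depth, m=2.0):
    """Independent recomputation of the whole chain with plain arithmetic."""
    variants = sorted(lib["hgvs_p"].unique(), key=lambda h: int(h[3:-1]))
    get = lambda df, h, cond, rep: float(
        df[(df.hgvs_p == h) & (df.condition == cond) & (df.replicate == rep)]["count"].iloc[0]
    )
    log_phi, cpm_pre = {}, {}
    for h in variants:
        for rep in (1, 2):
            fp_pre = (get(lib, h, "pre", rep) - get(wt, h, "wt_pre", rep)) / depth
            fp_post = (get(lib, h, "post", rep) - get(wt, h, "wt_post", rep)) / depth
            if fp_post <= 0:
                fp_post = 1.0 / depth
            log_phi[h, rep] = np.log2(fp_post / fp_pre)
            cpm_pre[h, rep] = 1e6 * get(lib, h, "pre", rep) / depth
    sd_emp = {
        h: np.std([log_phi[h, 1], log_phi[h, 2]], ddof=1) for h in variants
    }
    xs = [np.log(cpm_pre[h, r]) for h in variants for r in (1, 2) if sd_emp[h] > 0]
    ys = [np.log(sd_emp[h]) for h in variants for r in (1, 2) if sd_emp[h] > 0]
    xb, yb = np.mean(xs), np.mean(ys)
    slope = sum((x - xb) * (y - yb) for x, y in zip(xs, ys)) / sum(
        (x - xb) ** 2 for x in xs
    )
    intercept = yb - slope * xb

    combined = {}
    for h in variants:
        ws, vals, dfs = [], [], []
        for rep in (1, 2):
            sd_model = np.exp(slope * np.log(cpm_pre[h, rep]) + intercept)
            se2 = (m * sd_model**2 + 1 * sd_emp[h] ** 2) / (m + 1)
            ws.append(1.0 / se2)
            vals.append(log_phi[h, rep])
            dfs.append(m + 1)
        sw = sum(ws)
        mean = sum(w * v for w, v in zip(ws, vals)) / sw
        se = np.sqrt(1.0 / sw)
        combined[h] = (mean, se)
    phi = {h: 2.0 ** v[0] for h, v in combined.items()}
    med_non = np.median([phi[h] for h in variants if h.endswith("*")])
    med_syn = np.median([phi[h] for h in variants if h.endswith("L")])
    span = med_syn - med_non
    return {
        h: (
            (phi[h] - med_non) / span,
            phi[h] * np.log(2.0) * combined[h][1] / span,
        )
        for h in variants
    }


def test_scores_match_spreadsheet_oracle():
    lib, wt = _fixture_counts()
    scores = score_counts(lib, wt).set_index("hgvs_p")
    oracle = _oracle_scores(lib, wt, depth=100_000)
    assert len(oracle) == len(scores)
    for h, (score, se) in oracle.items():
        assert scores.at[h, "score"] == pytest.approx(score, abs=1e-9)
        assert scores.at[h, "se"] == pytest.approx(se, abs=1e-9)


class TestFrequencies:
    def test_cpm_arithmetic(self):
        df = pd.DataFrame(
            [dict(condition="pre", replicate=1, tile=1, hgvs_p="p.X1V",
                  position=1, from_aa="A", to_aa="V", vclass="missense",
                  count=13, depth=1_300_000)]
        )
        out = compute_frequencies(df)
        assert out["cpm"].iloc[0] == pytest.approx(10.0)

    def test_zero_count_zero_freq(self):
        df = pd.DataFrame(
            [dict(condition="pre", replicate=1, tile=1, hgvs_p="p.X1V",
                  position=1, from_aa="A", to_aa="V", vclass="missense",
                  count=0, depth=100)]
        )
        out = compute_frequencies(df)
        assert out["freq"].iloc[0] == 0.0 and out["cpm"].iloc[0] == 0.0

    def test_zero_depth_rejected(self):
        df = pd.DataFrame(
            [dict(condition="pre", replicate=1, tile=1, hgvs_p="p.X1V",
                  position=1, from_aa="A", to_aa="V", vclass="missense",
                  count=0, depth=0)]
        )
        with pytest.raises(ValueError, match="depth"):
            compute_frequencies(df)

    def test_duplicate_rows_rejected(self):
        row = dict(condition="pre", replicate=1, tile=1, hgvs_p="p.X1V",
                   position=1, from_aa="A", to_aa="V", vclass="missense",
                   count=5, depth=100)
        with pytest.raises(ValueError, match="duplicate"):
            compute_frequencies(pd.DataFrame([row, row]))


def _freq_tables(pre_count, wt_counts, depth=1_000_000):
    lib = compute_frequencies(pd.DataFrame(
        [dict(condition="pre", replicate=1, tile=1, hgvs_p="p.X1V",
              position=1, from_aa="A", to_aa="V", vclass="missense",
              count=pre_count, depth=depth)]
    ))
    wt = compute_frequencies(pd.DataFrame(
        [dict(condition="wt_pre", replicate=1, tile=1, hgvs_p=f"p.X{i + 1}V",
              position=i + 1, from_aa="A", to_aa="V", vclass="missense",
              count=c, depth=depth)
         for i, c in enumerate(wt_counts)]
    ))
    return lib, wt


class TestFilters:
    def test_raw_count_below_ten_flagged(self):
        lib, wt = _freq_tables(9, [0] * 10)
        flags = apply_filters(lib, wt)
        assert flags["low_count"].iloc[0]

    def test_cpm_exactly_ten_is_well_measured(self):
        lib, wt = _freq_tables(10, [0] * 10)  # 10 reads / 1e6 depth = 10 cpm
        flags = apply_filters(lib, wt)
        assert not flags["not_well_measured"].iloc[0]

    def test_zero_error_control_never_flags_positive_frequency(self):
        lib, wt = _freq_tables(50, [0] * 10)
        flags = apply_filters(lib, wt)
        assert not flags["below_wt_p90"].iloc[0]

    def test_empty_control_rejected(self):
        lib, wt = _freq_tables(50, [0])
        with pytest.raises(ValueError, match="WT-control"):
            apply_filters(lib, wt.iloc[0:0])


def _enrich_tables(cpms, depth=1_000_000):
    """cpms = dict with pre, post, wt_pre, wt_post counts-per-million."""
    def table(cond_counts, conds):
        return compute_frequencies(pd.DataFrame(
            [dict(condition=c, replicate=1, tile=1, hgvs_p="p.X1V",
                  position=1, from_aa="A", to_aa="V", vclass="missense",
                  count=int(cond_counts[c] * depth / 1e6), depth=depth)
             for c in conds]
        ))
    lib = table(cpms, ["pre", "post"])
    wt = table(cpms, ["wt_pre", "wt_post"])
    return lib, wt


class TestEnrichment:
    def test_corrected_ratio_arithmetic(self):
        lib, wt = _enrich_tables(dict(pre=50, post=90, wt_pre=10, wt_post=10))
        out = correct_and_enrich(lib, wt)
        assert out["phi"].iloc[0] == pytest.approx(2.0)  # (90-10)/(50-10)

    def test_nonpositive_corrected_pre_flagged(self):
        lib, wt = _enrich_tables(dict(pre=10, post=90, wt_pre=10, wt_post=0))
        out = correct_and_enrich(lib, wt)
        assert out["nonpositive_corrected_pre"].iloc[0]
        assert np.isnan(out["phi"].iloc[0])

    def test_depleted_variant_floored_at_one_pseudoread(self):
        lib, wt = _enrich_tables(dict(pre=50, post=5, wt_pre=10, wt_post=5))
        out = correct_and_enrich(lib, wt)
        f_pre = (50 - 10) / 1e6
        assert out["phi"].iloc[0] == pytest.approx((1 / 1e6) / f_pre)

    def test_missing_control_row_names_variant(self):
        lib, wt = _enrich_tables(dict(pre=50, post=90, wt_pre=10, wt_post=10))
        with pytest.raises(ValueError, match="p.X1V"):
            correct_and_enrich(lib, wt[wt.condition == "wt_pre"])


def _enrich_frame(n=40, sd=0.1, seed=5):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        mu = rng.normal(0, 1)
        cpm = rng.uniform(50, 500)
        for rep in (1, 2):
            rows.append(dict(hgvs_p=f"p.X{i + 1}V", replicate=rep, tile=1,
                             position=i + 1, from_aa="A", to_aa="V",
                             vclass="missense", cpm_pre=cpm,
                             log_phi=mu + rng.normal(0, sd),
                             nonpositive_corrected_pre=False))
    return pd.DataFrame(rows)


class TestRegularization:
    def test_zero_empirical_sd_keeps_positive_error(self):
        df = _enrich_frame()
        # force one variant's replicates equal
        df.loc[df.hgvs_p == "p.X1V", "log_phi"] = 1.234
        reg = regularize_errors(df, m=2.0)
        rec = reg[reg.hgvs_p == "p.X1V"].iloc[0]
        assert rec["se_reg"] == pytest.approx(
            rec["sd_model"] * np.sqrt(2.0 / 3.0)
        )
        assert rec["se_reg"] > 0

    def test_m_zero_returns_empirical_sd(self):
        reg = regularize_errors(_enrich_frame(), m=0.0)
        assert np.allclose(reg["se_reg"], reg["sd_emp"])

    def test_large_m_converges_to_model_sd(self):
        reg = regularize_errors(_enrich_frame(), m=1e9)
        assert np.allclose(reg["se_reg"], reg["sd_model"], rtol=1e-3)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="30"):
            regularize_errors(_enrich_frame(n=10))


def _combined_input(values_ses, dfs=None):
    rows = []
    for i, (v, s) in enumerate(values_ses):
        rows.append(dict(hgvs_p="p.X1V", replicate=i + 1, tile=1, position=1,
                         from_aa="A", to_aa="V", vclass="missense",
                         log_phi=v, se_reg=s, df=(dfs or [3] * len(values_ses))[i]))
    return pd.DataFrame(rows)


class TestCombination:
    def test_inverse_variance_weighting(self):
        out = combine_replicates(_combined_input([(1.0, 0.1), (0.5, 0.2)]))
        # (100*1.0 + 25*0.5) / 125
        assert out["log_phi"].iloc[0] == pytest.approx(0.9)

    def test_equal_errors_give_arithmetic_mean(self):
        out = combine_replicates(_combined_input([(1.0, 0.1), (0.4, 0.1)]))
        assert out["log_phi"].iloc[0] == pytest.approx(0.7)

    def test_single_replicate_passes_through(self):
        out = combine_replicates(_combined_input([(1.3, 0.07)]))
        assert out["log_phi"].iloc[0] == pytest.approx(1.3)
        assert out["se"].iloc[0] == pytest.approx(0.07)
        assert out["single_replicate"].iloc[0]


class TestRescaling:
    def _combined(self, non_phis, syn_phis, extra_phis=()):
        rows = []
        i = 0
        for phis, vclass, to in ((non_phis, "nonsense", "*"),
                                 (syn_phis, "synonymous", "L"),
                                 (extra_phis, "missense", "V")):
            for phi in phis:
                i += 1
                rows.append(dict(hgvs_p=f"p.X{i}{to}", position=i, from_aa="L",
                                 to_aa=to, vclass=vclass, tile=1,
                                 log_phi=np.log2(phi), se=0.1, df=3.0,
                                 single_replicate=False))
        return pd.DataFrame(rows)

    def test_anchor_medians_exact(self):
        rng = np.random.default_rng(0)
        df = self._combined(rng.uniform(0.01, 0.3, 15), rng.uniform(0.8, 1.4, 15))
        out = rescale_scores(df)
        assert np.median(out.loc[out.vclass == "nonsense", "score"]) == 0.0
        assert np.median(out.loc[out.vclass == "synonymous", "score"]) == 1.0

    def test_linear_midpoint(self):
        df = self._combined([0.2] * 11, [1.4] * 11, [0.8])
        out = rescale_scores(df)
        assert out.loc[out.vclass == "missense", "score"].iloc[0] == pytest.approx(0.5)

    def test_inverted_selection_rejected(self):
        df = self._combined([1.4] * 11, [0.2] * 11)
        with pytest.raises(ValueError, match="inverted|failed"):
            rescale_scores(df)

    def test_too_few_anchors_rejected(self):
        df = self._combined([0.2] * 5, [1.4] * 11)
        with pytest.raises(ValueError, match=">= 10"):
            rescale_scores(df)


def test_depth_scale_equivariance(small_run):
    lib, wt = small_run["lib_counts"], small_run["wt_counts"]
    scale = 10
    lib2 = lib.assign(count=lib["count"] * scale, depth=lib["depth"] * scale)
    wt2 = wt.assign(count=wt["count"] * scale, depth=wt["depth"] * scale)
    a = score_counts(lib, wt).set_index("hgvs_p")
    b = score_counts(lib2, wt2).set_index("hgvs_p")
    # the pseudo-read floor 1/depth differs by design; compare unfloored variants
    freqs, wfreqs = compute_frequencies(lib), compute_frequencies(wt)
    enrich = correct_and_enrich(freqs, wfreqs)
    floored = set(
        enrich.loc[
            (enrich["f_post"] - enrich["f_wt_post"]) <= 0, "hgvs_p"
        ]
    )
    keep = [h for h in a.index if h not in floored]
    assert np.allclose(a.loc[keep, "score"].astype(float),
                       b.loc[keep, "score"].astype(float), equal_nan=True)


def test_parameter_recovery_on_small_simulation(small_run, small_scores):
    truth = small_run["truth"].frame.set_index("hgvs_p")["true_effect"]
    sc = small_scores[small_scores["score"].notna()].set_index("hgvs_p")
    merged = pd.concat([sc["score"], truth], axis=1).dropna()
    r = np.corrcoef(merged["score"], merged["true_effect"])[0, 1]
    assert r > 0.9
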