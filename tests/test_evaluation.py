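"""ROC/AUC, DeLong, F1 curve and cumulative recovery, with independent oracles."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, rankdata

import maxmif as mx
from maxmif.errors import DegenerateInputError, EmptyDataError


def make_ranking(genes, scores):
    df = pd.DataFrame({"gene": genes, "s_maxmif": scores, "mutation_score": 0.0})
    df = df.sort_values(["s_maxmif", "gene"], ascending=[False, True]).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def pair_count_auc(scores, labels):
    """Exhaustive Mann-Whitney: correctly ordered pairs, ties count 1/2."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        genes = [f"g{i}" for i in range(10)]
        rk = make_ranking(genes, np.arange(10, 0, -1))
        ref = mx.ReferenceGeneSet("r", frozenset(genes[:3]))
        roc, auc = mx.roc_auc(rk, ref)
        assert auc == pytest.approx(1.0)
        assert tuple(roc[0]) == (0.0, 0.0)
        assert tuple(roc[-1]) == (1.0, 1.0)

    def test_constant_scores_give_half(self):
        genes = [f"g{i}" for i in range(10)]
        rk = make_ranking(genes, np.ones(10))
        ref = mx.ReferenceGeneSet("r", frozenset(genes[:4]))
        _, auc = mx.roc_auc(rk, ref)
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        genes = [f"g{i}" for i in range(5)]
        rk = make_ranking(genes, np.arange(5))
        with pytest.raises(DegenerateInputError):
            mx.roc_auc(rk, mx.ReferenceGeneSet("r", frozenset(genes)))
        with pytest.raises(DegenerateInputError):
            mx.roc_auc(rk, mx.ReferenceGeneSet("r", frozenset(["absent"])))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(40)]
        scores = rng.choice(np.linspace(0, 1, 15), size=40)  # force ties
        labels = rng.random(40) < 0.3
        if not labels.any() or labels.all():
            labels[0], labels[-1] = True, False
        rk = make_ranking(genes, scores)
        ref = mx.ReferenceGeneSet("r", frozenset(np.array(genes)[labels]))
        _, auc = mx.roc_auc(rk, ref)
        expected = pair_count_auc(scores, labels)
        assert auc == pytest.approx(expected, rel=1e-12)

    def test_roc_monotone(self, bench):
        _, m, net, ref = bench
        rk = mx.prioritize(m, net)
        roc, _ = mx.roc_auc(rk, ref)
        assert (np.diff(roc[:, 0]) >= 0).all()
        assert (np.diff(roc[:, 1]) >= 0).all()


def delong_fixture(seed=60, n=60, n_pos=15):
    """Fixed synthetic instance with two informative but different score vectors."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n)]
    labels = np.zeros(n, dtype=bool)
    labels[:n_pos] = True
    a = labels * 1.0 + rng.normal(0, 0.9, n)
    b = labels * 0.8 + rng.normal(0, 1.0, n)
    sa = pd.Series(a, index=genes)
    sb = pd.Series(b, index=genes)
    ref = mx.ReferenceGeneSet("r", frozenset(np.array(genes)[labels]))
    return sa, sb, ref, labels


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        sa, _, ref, _ = delong_fixture()
        res = mx.delong_compare(sa, sa.copy(), ref)
        assert res.p_value == 1.0
        assert res.z == 0.0

    def test_swap_negates_z_preserves_p(self):
        sa, sb, ref, _ = delong_fixture()
        r1 = mx.delong_compare(sa, sb, ref)
        r2 = mx.delong_compare(sb, sa, ref)
        assert r1.z == pytest.approx(-r2.z, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
        assert r1.auc_a == pytest.approx(r2.auc_b)

    def test_auc_matches_roc_auc(self):
        sa, sb, ref, labels = delong_fixture()
        res = mx.delong_compare(sa, sb, ref)
        assert res.auc_a == pytest.approx(pair_count_auc(sa.to_numpy(), labels), rel=1e-12)
        assert res.auc_b == pytest.approx(pair_count_auc(sb.to_numpy(), labels), rel=1e-12)

    def test_mismatched_universe_rejected(self):
        sa, sb, ref, _ = delong_fixture()
        with pytest.raises(DegenerateInputError):
            mx.delong_compare(sa, sb.iloc[:-1], ref)

    def test_p_within_ten_pct_of_paired_bootstrap(self):
        """DeLong p vs a 10,000-rep paired bootstrap of the AUC difference."""
        sa, sb, ref, labels = delong_fixture()
        res = mx.delong_compare(sa, sb, ref)
        rng = np.random.default_rng(1234)
        n = len(sa)
        reps = 10_000
        idx = rng.integers(0, n, size=(reps, n))
        lab = labels[idx]
        ok = lab.any(axis=1) & ~lab.all(axis=1)
        idx, lab = idx[ok], lab[ok]

        def boot_aucs(values):
            v = values[idx]
            r = rankdata(v, axis=1)
            mpos = lab.sum(axis=1)
            return ((r * lab).sum(axis=1) - mpos * (mpos + 1) / 2) / (mpos * (n - mpos))

        diffs = boot_aucs(sa.to_numpy()) - boot_aucs(sb.to_numpy())
        se = diffs.std(ddof=1)
        p_boot = 2 * norm.sf(abs(res.auc_a - res.auc_b) / se)
        assert res.p_value == pytest.approx(p_boot, rel=0.10)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
    def test_matches_r_proc_delong(self, tmp_path):
        """Cross-check z/p against the R pROC implementation of the same test."""
        sa, sb, ref, labels = delong_fixture()
        df = pd.DataFrame({"y": labels.astype(int), "a": sa.to_numpy(), "b": sb.to_numpy()})
        csv = tmp_path / "scores.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "delong.R"
        script.write_text(
            "suppressMessages(library(pROC))\n"
            f"d <- read.csv('{csv}')\n"
            "ra <- roc(d$y, d$a, direction='<', quiet=TRUE)\n"
            "rb <- roc(d$y, d$b, direction='<', quiet=TRUE)\n"
            "t <- roc.test(ra, rb, method='delong', paired=TRUE)\n"
            "cat(sprintf('%.17g', c(t$statistic, t$p.value, auc(ra), auc(rb))), sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        ).stdout.split()
        z_r, p_r, auc_a_r, auc_b_r = map(float, out)
        res = mx.delong_compare(sa, sb, ref)
        assert res.auc_a == pytest.approx(auc_a_r, rel=1e-9)
        assert res.auc_b == pytest.approx(auc_b_r, rel=1e-9)
        assert res.z == pytest.approx(z_r, rel=1e-6)
        assert res.p_value == pytest.approx(p_r, rel=1e-6)


class TestF1Curve:
    def test_closed_form_when_top_k_all_reference(self):
        members = [f"r{i}" for i in range(30)]
        others = [f"o{i}" for i in range(70)]
        rk = make_ranking(members + others, np.arange(100, 0, -1))
        ref = mx.ReferenceGeneSet("r", frozenset(members))
        f1 = mx.f1_curve(rk, ref, max_rank=30)
        for k in (1, 5, 17, 30):
            assert f1.loc[k] == pytest.approx(2 * k / (k + 30), rel=1e-12)

    def test_zero_when_no_reference_in_top_k(self):
        rk = make_ranking(["a", "b", "r1"], [3.0, 2.0, 1.0])
        ref = mx.ReferenceGeneSet("r", frozenset(["r1"]))
        f1 = mx.f1_curve(rk, ref, max_rank=2)
        assert (f1 == 0).all()

    def test_recall_uses_full_reference_size(self):
        # r2 is not in the ranking universe; the denominator still counts it
        rk = make_ranking(["r1", "x"], [2.0, 1.0])
        ref = mx.ReferenceGeneSet("r", frozenset(["r1", "r2"]))
        f1 = mx.f1_curve(rk, ref, max_rank=1)
        assert f1.loc[1] == pytest.approx(2 * 1.0 * 0.5 / 1.5)

    def test_matches_recount_oracle(self):
        rng = np.random.default_rng(77)
        genes = [f"g{i}" for i in range(80)]
        rk = make_ranking(genes, rng.random(80))
        ref = mx.ReferenceGeneSet("r", frozenset(rng.choice(genes, 25, replace=False)))
        f1 = mx.f1_curve(rk, ref, max_rank=80)
        ordered = list(rk["gene"])
        for k in range(1, 81):
            hits = len(set(ordered[:k]) & ref.members)
            prec, rec = hits / k, hits / len(ref)
            expected = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
            assert f1.loc[k] == pytest.approx(expected, rel=1e-12)
        assert ((f1 >= 0) & (f1 <= 1)).all()


class TestCumulativeRecovery:
    def test_all_top20_reference(self):
        members = [f"r{i}" for i in range(20)]
        rk = make_ranking(members + ["x", "y"], np.arange(22, 0, -1))
        ref = mx.ReferenceGeneSet("r", frozenset(members))
        assert mx.cumulative_recovery(rk, ref)[20] == 20

    def test_empty_overlap_all_zero(self):
        rk = make_ranking(["a", "b"], [2.0, 1.0])
        ref = mx.ReferenceGeneSet("r", frozenset(["zzz"]))
        assert set(mx.cumulative_recovery(rk, ref).values()) == {0}

    def test_matches_recount_and_monotone(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(600)]
        rk = make_ranking(genes, rng.random(600))
        ref = mx.ReferenceGeneSet("r", frozenset(rng.choice(genes, 40, replace=False)))
        rec = mx.cumulative_recovery(rk, ref)
        ordered = list(rk["gene"])
        for k, count in rec.items():
            assert count == len(set(ordered[:k]) & ref.members)
            assert count <= min(k, len(ref))
        counts = [rec[k] for k in sorted(rec)]
        assert counts == sorted(counts)

    def test_invariant_to_nonreference_relabeling(self):
        rng = np.random.default_rng(21)
        genes = [f"g{i}" for i in range(100)]
        scores = rng.random(100)
        rk = make_ranking(genes, scores)
        ref = mx.ReferenceGeneSet("r", frozenset(genes[:10]))
        relabeled = [g if g in ref.members else f"zz_{g}" for g in genes]
        rk2 = make_ranking(relabeled, scores)
        assert mx.cumulative_recovery(rk, ref) == mx.cumulative_recovery(rk2, ref)
        pd.testing.assert_series_equal(mx.f1_curve(rk, ref), mx.f1_curve(rk2, ref))


class TestReferenceSetIO:
    def test_load_skips_comments(self, tmp_path):
        p = tmp_path / "ref.txt"
        p.write_text("# curated list\nTP53\nKRAS\n\nEGFR\n")
        ref = mx.load_gene_set(p)
        assert ref.members == {"TP53", "KRAS", "EGFR"}

    def test_empty_set_rejected(self, tmp_path):
        p = tmp_path / "ref.txt"
        p.write_text("# nothing here\n")
        with pytest.raises(EmptyDataError):
            mx.load_gene_set(p)

    def test_round_trip(self, tmp_path):
        ref = mx.ReferenceGeneSet("x", frozenset({"A", "B", "C"}))
        p = tmp_path / "out.txt"
        mx.write_gene_set(ref, p)
        assert mx.load_gene_set(p, name="x").members == ref.members
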