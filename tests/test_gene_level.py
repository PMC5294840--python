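import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seqgsa.datatypes import CountMatrix
from seqgsa.gene_level import (
    compute_gene_z,
    equalize_library_sizes,
    estimate_common_dispersion,
    exact_nb_test,
    p_to_z,
    z_for_masks,
)


def _cm(rows, groups, genes=None):
    rows = np.atleast_2d(rows)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    cols = [f"s{j}" for j in range(rows.shape[1])]
    return CountMatrix(pd.DataFrame(rows, index=genes, columns=cols), np.asarray(groups))


class TestExactNBTest:
    def test_poisson_conditional_binomial_example(self):
        # gene with group sums (0, 10) plus a balancing gene keeping library
        # sizes equal: two-sided tail of Binomial(10, 0.5) at 0 = 2 * 0.5**10
        cm = _cm([[0, 0, 5, 5], [5, 5, 0, 0]], ["c", "c", "t", "t"])
        res = dict((g, (p, s)) for g, p, s in exact_nb_test(cm, dispersion=0))
        assert res["g0"][0] == pytest.approx(2 * 0.5**10)
        assert res["g0"][1] == 1
        assert res["g1"][1] == -1

    def test_identical_counts_give_p_one_sign_zero(self):
        cm = _cm([[3, 4, 3, 4]], ["c", "c", "t", "t"])
        (_, p, s), = exact_nb_test(cm, dispersion=0)
        assert p == 1.0
        assert s == 0

    def test_all_zero_gene(self):
        cm = _cm([[0, 0, 0, 0], [1, 1, 1, 1]], ["c", "c", "t", "t"])
        (_, p, s) = exact_nb_test(cm, dispersion=0)[0]
        assert p == 1.0
        assert s == 0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            _cm([[1, 2, 3]], ["a", "a", "a"])

    def test_dispersion_zero_limit_matches_binomial(self):
        cm = _cm([[3, 1, 7, 9], [2, 2, 2, 3]], ["c", "c", "t", "t"])
        p0 = np.array([p for _, p, _ in exact_nb_test(cm, dispersion=0)])
        p_eps = np.array([p for _, p, _ in exact_nb_test(cm, dispersion=1e-12)])
        assert np.all(np.abs(p0 - p_eps) < 1e-9)

    def test_null_poisson_pvalues_conservative(self, rng):
        # conditional exact test is discrete, hence stochastically >= uniform
        n = 10_000
        counts = rng.poisson(100, size=(n, 8))
        cm = _cm(counts, ["c"] * 4 + ["t"] * 4)
        p = np.array([p for _, p, _ in exact_nb_test(cm, dispersion=0)])
        for alpha in (0.01, 0.05, 0.2):
            se = np.sqrt(alpha * (1 - alpha) / n)
            assert (p < alpha).mean() <= alpha + 3 * se

    def test_auto_dispersion_near_zero_for_poisson(self, rng):
        counts = rng.poisson(150, size=(2000, 8))
        cm = _cm(counts, ["c"] * 4 + ["t"] * 4)
        assert estimate_common_dispersion(cm) < 0.02

    def test_matches_edger_exact_test(self, rng, tmp_path):
        """Independent oracle: edgeR's exactTest with fixed dispersion."""
        mu = rng.uniform(20, 300, 25)
        r = 1 / 0.1
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(25, 8))
        counts[:4, 4:] = rng.negative_binomial(
            r, r / (r + 2 * mu[:4, None]), size=(4, 4)
        )
        df = pd.DataFrame(counts, index=[f"g{i}" for i in range(25)],
                          columns=list("abcdefgh"))
        df.to_csv(tmp_path / "counts.tsv", sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.delim("{tmp_path}/counts.tsv", row.names=1))
            grp <- factor(c(rep("c",4), rep("t",4)), levels=c("c","t"))
            d <- DGEList(counts=x, group=grp, lib.size=rep(1e6, 8))
            d$samples$norm.factors <- 1
            res <- exactTest(d, dispersion=0.1)
            write.csv(data.frame(gene=rownames(res$table), p=res$table$PValue,
                                 lfc=res$table$logFC),
                      "{tmp_path}/edger.csv", row.names=FALSE)
        """)
        (tmp_path / "xc.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "xc.R")], check=True,
                       capture_output=True)
        cm = CountMatrix(df, np.array(["c"] * 4 + ["t"] * 4))
        mine = pd.DataFrame(
            exact_nb_test(cm, dispersion=0.1, equalize=False),
            columns=["gene", "p", "sign"],
        ).set_index("gene")
        edger = pd.read_csv(tmp_path / "edger.csv").set_index("gene")
        joined = mine.join(edger, rsuffix="_edger")
        assert np.abs(joined["p"] - joined["p_edger"]).max() < 1e-4
        nonzero = joined["sign"] != 0
        assert (np.sign(joined.loc[nonzero, "lfc"]) == joined.loc[nonzero, "sign"]).all()


class TestPToZ:
    @pytest.mark.parametrize(
        "p, sign, expected",
        [(1.0, 1, 0.0), (0.05, -1, -1.95996), (0.0, 1, 8.0), (1.0, 0, 0.0)],
    )
    def test_examples(self, p, sign, expected):
        assert p_to_z(p, sign) == pytest.approx(expected, abs=1e-5)

    @given(st.floats(1e-12, 1.0), st.sampled_from([-1, 1]))
    def test_antisymmetric_in_sign(self, p, sign):
        assert p_to_z(p, sign) == pytest.approx(-p_to_z(p, -sign))

    @given(st.floats(1e-9, 0.999), st.floats(1e-9, 0.999))
    def test_monotone_decreasing_in_p(self, p1, p2):
        lo, hi = sorted((p1, p2))
        assert p_to_z(lo, 1) >= p_to_z(hi, 1)

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            p_to_z(1.5, 1)


class TestComputeGeneZ:
    def test_custom_method_pass_through(self):
        cm = _cm([[1, 2, 3, 4]] * 3, ["c", "c", "t", "t"])

        def fixed(cm):
            return [(g, 0.05, -1) for g in cm.gene_ids]

        out = compute_gene_z(cm, method=fixed)
        assert np.allclose(out["z"], p_to_z(0.05, -1))

    def test_rejects_out_of_range_p(self):
        cm = _cm([[1, 2, 3, 4]], ["c", "c", "t", "t"])
        with pytest.raises(ValueError, match="outside"):
            compute_gene_z(cm, method=lambda cm: [("g0", 1.2, 1)])

    def test_single_gene(self):
        cm = _cm([[5, 6, 7, 8]], ["c", "c", "t", "t"])
        out = compute_gene_z(cm, dispersion=0)
        assert len(out) == 1

    def test_null_z_mean_zero_sd_near_one(self, rng):
        counts = rng.poisson(100, size=(10_000, 8))
        cm = _cm(counts, ["c"] * 4 + ["t"] * 4)
        z = compute_gene_z(cm, dispersion=0)["z"].to_numpy()
        assert abs(z.mean()) < 0.04
        assert 0.85 < z.std() < 1.05


def test_z_for_masks_matches_per_gene_path(rng):
    counts = rng.poisson(80, size=(50, 8))
    # balance library sizes so neither path rescales counts
    pad = counts.sum(axis=0).max() - counts.sum(axis=0)
    counts = np.vstack([counts, pad])
    cm = _cm(counts, ["c"] * 4 + ["t"] * 4)
    masks = np.array([cm.reference_mask, np.roll(cm.reference_mask, 1)])
    Z = z_for_masks(cm, masks, dispersion=0)
    direct = compute_gene_z(cm, dispersion=0)["z"].to_numpy()
    assert np.allclose(Z[:, 0], direct)


def test_equalize_library_sizes_noop_when_equal(rng):
    counts = np.array([[5, 5, 5, 5], [3, 3, 3, 3]])
    cm = _cm(counts, ["c", "c", "t", "t"])
    assert equalize_library_sizes(cm) is cm
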