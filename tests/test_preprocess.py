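"""CPM, gene filtering, log2 and batch (site) correction."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from ultradian.nlr import fit_sinusoid
from ultradian.preprocess import (
    CPM_THRESHOLD,
    DataError,
    ExpressionMatrix,
    GeneAnnotation,
    StageError,
    batch_adjust,
    filter_genes,
    log2_transform,
    to_cpm,
)


def _counts(values, genes=None, subjects=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    subjects = subjects or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=subjects), "counts")


def test_cpm_single_gene_full_library():
    cpm = to_cpm(_counts([[2.0, 4.0]]))
    assert np.allclose(cpm.data.to_numpy(), [[1e6, 1e6]])
    assert cpm.stage == "cpm"


def test_cpm_column_sums_are_one_million(rng):
    counts = _counts(rng.integers(0, 500, size=(50, 10)))
    cpm = to_cpm(counts)
    assert np.allclose(cpm.data.sum(axis=0), 1e6, atol=1e-6)


def test_cpm_zero_total_subject_named():
    mat = _counts([[1.0, 0.0], [2.0, 0.0]])
    with pytest.raises(DataError, match="s1"):
        to_cpm(mat)


def test_stage_order_is_enforced():
    counts = _counts([[1.0, 2.0]] * 6)
    with pytest.raises(StageError):
        log2_transform(counts)  # cannot log2 raw counts
    with pytest.raises(StageError):
        batch_adjust(counts, ["a", "a"])
    with pytest.raises(StageError):
        to_cpm(to_cpm(counts))


def _annotation(genes, chroms):
    return GeneAnnotation(pd.DataFrame({"gene_id": genes, "chromosome": chroms}))


def test_filter_boundary_is_inclusive_at_half():
    # cpm > 1 in exactly half the subjects -> retained
    data = pd.DataFrame(
        [[2.0, 2.0, 0.5, 0.5]], index=["g0"], columns=list("abcd")
    )
    mat = ExpressionMatrix(data, "cpm")
    keep = filter_genes(mat, _annotation(["g0"], ["1"]))
    assert keep == ["g0"]


def test_filter_drops_chrY_and_unmapped():
    data = pd.DataFrame(
        np.full((3, 4), 10.0), index=["auto", "ychrom", "orphan"], columns=list("abcd")
    )
    mat = ExpressionMatrix(data, "cpm")
    keep = filter_genes(mat, _annotation(["auto", "ychrom"], ["1", "Y"]))
    assert keep == ["auto"]


def test_filter_matches_bruteforce(rng):
    G, N = 200, 20
    cpm_vals = rng.gamma(1.0, 2.0, size=(G, N))
    genes = [f"g{i}" for i in range(G)]
    chroms = rng.choice(["1", "2", "X", "Y"], size=G)
    mapped = rng.random(G) > 0.05
    ann = _annotation(
        [g for g, m in zip(genes, mapped) if m],
        [c for c, m in zip(chroms, mapped) if m],
    )
    mat = ExpressionMatrix(pd.DataFrame(cpm_vals, index=genes, columns=range(N)), "cpm")
    keep = filter_genes(mat, ann)

    expected = []
    for i, g in enumerate(genes):
        n_pass = sum(1 for v in cpm_vals[i] if v > CPM_THRESHOLD)
        if n_pass / N >= 0.5 and mapped[i] and chroms[i] != "Y":
            expected.append(g)
    assert keep == expected


@pytest.mark.parametrize("cpm,offset,expected", [(1.0, 1.0, 1.0), (0.0, 1.0, 0.0)])
def test_log2_values(cpm, offset, expected):
    mat = ExpressionMatrix(pd.DataFrame([[cpm] * 2], index=["g"], columns=["a", "b"]), "cpm")
    out = log2_transform(mat, offset=offset)
    assert out.data.iloc[0, 0] == pytest.approx(expected)
    assert f"log2(cpm+{offset:g})" in out.provenance[-1]


def test_log2_round_trip(rng):
    vals = rng.gamma(2.0, 5.0, size=(10, 5))
    mat = ExpressionMatrix(pd.DataFrame(vals, index=[f"g{i}" for i in range(10)]), "cpm")
    out = log2_transform(mat, offset=1.0)
    back = 2.0 ** out.data.to_numpy() - 1.0
    assert np.allclose(back, vals, atol=1e-12)


def _log2mat(X):
    return ExpressionMatrix(
        pd.DataFrame(X, index=[f"g{i}" for i in range(X.shape[0])],
                     columns=[f"s{j}" for j in range(X.shape[1])]),
        "log2",
    )


def test_single_batch_is_identity():
    X = np.random.default_rng(1).normal(5, 1, (20, 10))
    out = batch_adjust(_log2mat(X), ["one"] * 10)
    assert np.allclose(out.data.to_numpy(), X, atol=1e-8)
    assert out.stage == "adjusted"


def test_small_batch_rejected():
    X = np.zeros((5, 5))
    with pytest.raises(DataError, match="< 2 subjects"):
        batch_adjust(_log2mat(X), ["a", "a", "a", "a", "b"])


@pytest.mark.parametrize("eb", [True, False])
def test_common_site_shift_removed(rng, eb):
    """A shared site offset is removed by both the EB and plain routes."""
    G, half = 100, 15
    X = rng.normal(5, 1, (G, 2 * half))
    X[:, half:] += 0.8
    batches = ["P"] * half + ["M"] * half
    out = batch_adjust(_log2mat(X), batches, empirical_bayes=eb).data.to_numpy()
    diff = out[:, half:].mean(axis=1) - out[:, :half].mean(axis=1)
    # the systematic 0.8 offset is gone; the EB route intentionally leaves
    # per-gene batch-mean *sampling noise* (sd ~ sqrt(2/n)) in place, while
    # the plain route zeroes observed batch means exactly
    assert abs(diff.mean()) < 0.06
    assert np.abs(diff).mean() < (0.05 if not eb else 3.0 * np.sqrt(2.0 / half) / np.sqrt(np.pi / 2))


def test_gene_specific_shift_removal(rng):
    """Per-gene site shifts: the plain route removes them exactly; the EB
    route removes the common component and shrinks the gene-specific part
    (it borrows strength across genes, by design)."""
    G, half = 100, 15
    X = rng.normal(5, 1, (G, 2 * half))
    shift = rng.normal(0.8, 0.2, G)
    X[:, half:] += shift[:, None]
    batches = ["P"] * half + ["M"] * half
    plain = batch_adjust(_log2mat(X), batches, empirical_bayes=False).data.to_numpy()
    diff_plain = plain[:, half:].mean(axis=1) - plain[:, :half].mean(axis=1)
    assert np.abs(diff_plain).max() < 1e-8

    eb = batch_adjust(_log2mat(X), batches, empirical_bayes=True).data.to_numpy()
    diff_eb = eb[:, half:].mean(axis=1) - eb[:, :half].mean(axis=1)
    assert abs(diff_eb.mean()) < 0.05  # common 0.8 offset gone
    assert np.abs(diff_eb).mean() < np.abs(shift).mean() / 2  # net reduction


def test_balanced_grand_means_preserved_exactly_without_eb(rng):
    X = rng.normal(5, 1, (50, 20))
    out = batch_adjust(_log2mat(X), ["a"] * 10 + ["b"] * 10, empirical_bayes=False)
    assert np.allclose(out.data.mean(axis=1), X.mean(axis=1), atol=1e-6)


def test_balanced_grand_means_approximately_preserved_with_eb(rng):
    X = rng.normal(5, 1, (50, 20))
    out = batch_adjust(_log2mat(X), ["a"] * 10 + ["b"] * 10, empirical_bayes=True)
    assert np.allclose(out.data.mean(axis=1), X.mean(axis=1), atol=0.05)


def test_adjustment_preserves_balanced_rhythm(rng, uneven_zt):
    """Site correction must not destroy a site-balanced 12 h rhythm."""
    n = uneven_zt.size
    rhythm = 1.2 * np.cos(2 * np.pi * (uneven_zt - 4) / 12.0)
    X = rng.normal(5, 0.8, (40, n))
    X[0] += rhythm
    batches = np.array(["P", "M"] * (n // 2))
    X[:, batches == "M"] += 0.6  # pure site offset
    out = batch_adjust(_log2mat(X), list(batches)).data.to_numpy()
    before = fit_sinusoid(X[0], uneven_zt, 12.0).r2
    after = fit_sinusoid(out[0], uneven_zt, 12.0).r2
    assert abs(after - before) < 0.05


def test_combat_matches_reference_r_implementation(rng, tmp_path):
    """Native EB adjustment agrees with the Bioconductor reference on a
    small two-site matrix (independent oracle via Rscript)."""
    G, half = 30, 10
    X = rng.normal(5, 1, (G, 2 * half))
    X[:, half:] += rng.normal(0.8, 0.3, (G, 1))
    df = pd.DataFrame(X, index=[f"g{i}" for i in range(G)],
                      columns=[f"s{j}" for j in range(2 * half)])
    batches = ["P"] * half + ["M"] * half
    in_tsv = tmp_path / "in.tsv"
    out_tsv = tmp_path / "r_out.tsv"
    df.to_csv(in_tsv, sep="\t")
    script = tmp_path / "combat.R"
    script.write_text(
        "suppressMessages(library(sva))\n"
        f"x <- as.matrix(read.table('{in_tsv}', sep='\\t', header=TRUE, row.names=1))\n"
        f"b <- c({', '.join(repr(b) for b in batches)})\n"
        "out <- ComBat(dat=x, batch=b, par.prior=TRUE, prior.plots=FALSE)\n"
        f"write.table(out, '{out_tsv}', sep='\\t', quote=FALSE)\n"
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    reference = pd.read_csv(out_tsv, sep="\t", index_col=0)
    ours = batch_adjust(ExpressionMatrix(df, "log2"), batches)
    assert np.abs(ours.data.to_numpy() - reference.to_numpy()).max() < 1e-6


def test_duplicate_ids_rejected():
    with pytest.raises(DataError, match="duplicate gene ids"):
        ExpressionMatrix(pd.DataFrame(np.ones((2, 2)), index=["g", "g"]), "counts")
    with pytest.raises(DataError, match="negative|non-negative"):
        ExpressionMatrix(pd.DataFrame([[-1.0]], index=["g"]), "counts")
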