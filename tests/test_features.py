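import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ecmpredict.features as feat
from ecmpredict.io import AA_ORDER, AAIndexTable, DomainCatalog, PSSM, ProteinRecord
from conftest import gm21_oracle


def _table(**values):
    """One-property amino-acid index table; unspecified residues get 0."""
    row = {res: float(values.get(res, 0.0)) for res in AA_ORDER}
    return AAIndexTable(values=pd.DataFrame([row], index=["prop"]))


CATALOG = DomainCatalog(accessions=tuple(f"IPR{i}" for i in range(1, 11)))


# ---------------------------------------------------------------------------
# Domain flags

def test_domain_features_no_annotation_is_all_ones():
    # the published encoding scores an absent domain as 1
    vec = feat.domain_features("pX", {}, CATALOG)
    assert vec.tolist() == [1.0] * 10


def test_domain_features_present_domain_scores_zero():
    vec = feat.domain_features("p1", {"p1": {"IPR5"}}, CATALOG)
    expected = [1.0] * 10
    expected[4] = 0.0  # catalog position of IPR5
    assert vec.tolist() == expected


def test_domain_polarities_are_complementary():
    ann = {"p1": {"IPR2", "IPR9"}}
    printed = feat.domain_features("p1", ann, CATALOG, polarity="as_printed")
    presence = feat.domain_features("p1", ann, CATALOG, polarity="presence")
    assert (printed + presence == 1.0).all()


# ---------------------------------------------------------------------------
# Physicochemical means

@pytest.mark.parametrize(
    "sequence, table, expected",
    [
        ("AAAA", _table(A=2.5), 2.5),
        ("AC", _table(A=1, C=3), 2.0),
        ("AXC", _table(A=1, C=3), 2.0),  # X skipped, effective length 2
    ],
)
def test_physchem_mean(sequence, table, expected):
    assert feat.physchem_features(sequence, table)[0] == pytest.approx(expected)


def test_physchem_all_unknown_errors():
    with pytest.raises(ValueError, match="unknown residues"):
        feat.physchem_features("XXX", _table())


def test_physchem_bounded_by_residue_extremes(aaindex):
    values = feat.physchem_features("ACDEFGHIKLMNPQRSTVWY", aaindex)
    table = aaindex.values[list(AA_ORDER)].to_numpy()
    assert (values >= table.min(axis=1) - 1e-12).all()
    assert (values <= table.max(axis=1) + 1e-12).all()


# ---------------------------------------------------------------------------
# PSSM standardization and grey model

def test_standardize_logistic_values():
    pssm = PSSM(protein_id="p", scores=np.zeros((4, 20), dtype=int))
    assert (feat.standardize_pssm(pssm) == 0.5).all()
    graded = PSSM(protein_id="p", scores=np.tile([[-10, 0, 10] + [0] * 17], (4, 1)))
    std = feat.standardize_pssm(graded)
    assert std[0, 0] < std[0, 1] < std[0, 2]  # monotone in the score
    assert 0 < std.min() and std.max() < 1


def test_standardize_rejects_short_proteins():
    pssm = PSSM(protein_id="tiny", scores=np.zeros((3, 20), dtype=int))
    with pytest.raises(ValueError, match="at least 4"):
        feat.standardize_pssm(pssm)


def test_gm21_constant_column_is_zero():
    params = feat.fit_gm21([2.0, 2.0, 2.0, 2.0])
    assert params.as_array() == pytest.approx([0.0, 0.0, 0.0], abs=1e-12)


def test_gm21_matches_oracle_on_ramp():
    params = feat.fit_gm21([1, 2, 3, 4, 5]).as_array()
    assert params == pytest.approx(gm21_oracle([1, 2, 3, 4, 5]), abs=1e-10)


@settings(max_examples=150, deadline=None)
@given(
    st.lists(st.floats(min_value=0.01, max_value=100), min_size=4, max_size=40),
    st.floats(min_value=0.1, max_value=10),
)
def test_gm21_matches_oracle_including_scaling(column, scale):
    """The fit equals the independent pinv oracle, also under positive scaling."""
    for series in (column, [scale * v for v in column]):
        got = feat.fit_gm21(series).as_array()
        want = gm21_oracle(series)
        assert np.max(np.abs(got - want)) < 1e-8


def test_gm21_rejects_nonpositive():
    with pytest.raises(ValueError, match="positive"):
        feat.fit_gm21([1.0, 0.0, 2.0, 3.0])


def test_pssm_features_all_zero_matrix():
    pssm = PSSM(protein_id="p", scores=np.zeros((4, 20), dtype=int))
    vec = feat.pssm_features(pssm)
    assert vec.shape == (80,)
    assert vec[:20] == pytest.approx([0.5] * 20)
    assert vec[20:] == pytest.approx([0.0] * 60, abs=1e-12)


def test_pssm_row_permutation_keeps_means_only():
    rng = np.random.default_rng(0)
    scores = rng.integers(-10, 11, size=(12, 20))
    base = feat.pssm_features(PSSM(protein_id="p", scores=scores))
    permuted = feat.pssm_features(PSSM(protein_id="p", scores=scores[::-1].copy()))
    assert base[:20] == pytest.approx(permuted[:20])
    assert not np.allclose(base[20:], permuted[20:])


# ---------------------------------------------------------------------------
# Assembly

def test_extract_features_dimensions_and_determinism(small_dataset, aaindex):
    rec = small_dataset.records[0]
    args = (rec, small_dataset.annotations, small_dataset.pssms[rec.id],
            small_dataset.catalog, aaindex)
    vec = feat.extract_features(*args)
    assert len(vec) == 167
    assert np.isfinite(vec.to_numpy()).all()
    assert vec.equals(feat.extract_features(*args))
    # block value ranges
    assert set(vec.iloc[:63].unique()) <= {0.0, 1.0}
    assert ((vec.iloc[87:107] > 0) & (vec.iloc[87:107] < 1)).all()  # PSSM means


def test_extract_features_domain_block_independence(small_dataset, aaindex):
    rec = small_dataset.records[0]
    pssm = small_dataset.pssms[rec.id]
    base = feat.extract_features(rec, {}, pssm, small_dataset.catalog, aaindex)
    annotated = feat.extract_features(
        rec, {rec.id: {small_dataset.catalog.accessions[0]}}, pssm,
        small_dataset.catalog, aaindex,
    )
    diff = (base != annotated).to_numpy()
    assert diff[:63].sum() == 1 and not diff[63:].any()


def test_extract_features_length_mismatch():
    rec = ProteinRecord(id="p", sequence="ACDEF")
    pssm = PSSM(protein_id="p", scores=np.zeros((4, 20), dtype=int))
    with pytest.raises(ValueError, match="length"):
        feat.extract_features(rec, {}, pssm, CATALOG, _table(A=1))
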