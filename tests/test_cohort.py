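"""Cohort data model, phenotype/matrix I/O, lattice ROIs, handedness imputation."""

import numpy as np
import pytest

from fcloo import (
    AssociationMatrix,
    CohortError,
    PhenotypeRecord,
    ROISet,
    build_lattice_rois,
    impute_handedness,
    n_connections,
    read_matrix,
    read_phenotypes,
    write_matrix,
    write_phenotypes,
)
from fcloo.cohort import connection_pairs, matrix_from_condensed


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

PHENO_TEXT = """subject_id\tsite\tdiagnosis\tage\tgender\thandedness\teyes\tn_volumes_acquired\tn_volumes_retained\tados_social_comm\tadi_r_social\tadi_r_verbal\tverbal_iq\tperformance_iq\tsrs_total\tvineland_composite
s1\tA\tautism\t12.5\tmale\t+0.8\topen\t150\t120\t11\t20\t15\t100\t101\t95\t
s2\tA\tcontrol\t20.0\tfemale\t0\tclosed\t150\t150\t1\tNA\tNA\t115\t110\t20\t104
s3\tB\tcontrol\t30.0\tmale\tleft\t\t200\t180\tNA\tNA\tNA\t108\t109\t25\t102
"""


def test_read_phenotypes_parses_levels_and_missingness(tmp_path):
    """Quantitative handedness converts by sign; blanks and NA stay missing."""
    p = tmp_path / "pheno.tsv"
    p.write_text(PHENO_TEXT)
    recs = read_phenotypes(p)
    assert len(recs) == 3
    assert recs[0].handedness == "right"  # +0.8
    assert recs[1].handedness == "ambidextrous"  # 0
    assert recs[2].handedness == "left"
    assert recs[0].vineland_composite is None
    assert recs[1].adi_r_social is None
    assert recs[2].eyes == "unknown"
    assert recs[1].srs_total == 20.0


def test_phenotype_round_trip_preserves_fields_and_missingness(tmp_path):
    p = tmp_path / "pheno.tsv"
    p.write_text(PHENO_TEXT)
    recs = read_phenotypes(p)
    out = tmp_path / "copy.tsv"
    write_phenotypes(recs, out)
    back = read_phenotypes(out)
    assert back == recs


@pytest.mark.parametrize(
    "mutation,message",
    [
        ("autism\t12.5", None),  # control row: no error
        ("asd\t12.5", "diagnosis"),
        ("autism\t-3", "age"),
    ],
)
def test_read_phenotypes_rejects_bad_rows(tmp_path, mutation, message):
    header = PHENO_TEXT.splitlines()[0]
    row = f"sX\tA\t{mutation}\tmale\tright\topen\t150\t120\t\t\t\t\t\t\t"
    text = header + "\n" + row + "\n" + "\n".join(PHENO_TEXT.splitlines()[1:]) + "\n"
    p = tmp_path / "pheno.tsv"
    p.write_text(text)
    if message is None:
        assert len(read_phenotypes(p)) == 4
    else:
        with pytest.raises(CohortError, match=message):
            read_phenotypes(p)


def test_duplicate_subject_id_rejected(tmp_path):
    text = PHENO_TEXT + PHENO_TEXT.splitlines()[1] + "\n"
    p = tmp_path / "pheno.tsv"
    p.write_text(text)
    with pytest.raises(CohortError, match="duplicate"):
        read_phenotypes(p)


# ---------------------------------------------------------------------------
# handedness imputation
# ---------------------------------------------------------------------------


def _rec(i, age, gender="male", site="A", handedness="right"):
    return PhenotypeRecord(
        subject_id=f"s{i}", site=site, diagnosis="control" if i % 2 else "autism",
        age=age, gender=gender, handedness=handedness,
    )


def test_impute_unanimous_neighborhood():
    recs = [_rec(i, 10.0 + i) for i in range(9)] + [_rec(9, 14.0, handedness=None)]
    out = impute_handedness(recs, k=3)
    assert out[9].handedness == "right"
    assert [r.handedness for r in out[:9]] == ["right"] * 9


def test_impute_identity_when_nothing_missing():
    recs = [_rec(i, 10.0 + i) for i in range(6)]
    assert impute_handedness(recs, k=3) == recs


def test_impute_matches_exhaustive_sort_oracle(rng):
    """Masked labels equal the majority among k nearest by brute-force sort."""
    ages = rng.uniform(6, 60, size=20)
    hand = np.where(ages < 30, "right", "left")
    recs = [_rec(i, float(ages[i]), handedness=str(hand[i])) for i in range(20)]
    masked = [3, 17]
    for m in masked:
        recs[m] = PhenotypeRecord(**{**recs[m].__dict__, "handedness": None})
    out = impute_handedness(recs, k=5)

    # brute-force oracle in the same feature space (all same gender/site ->
    # distance reduces to standardized age)
    known = [i for i in range(20) if i not in masked]
    age_z = (ages - ages.mean()) / ages.std()
    for m in masked:
        order = sorted(known, key=lambda j: (abs(age_z[j] - age_z[m])))
        votes = [str(hand[j]) for j in order[:5]]
        expected = max(("right", "left"), key=votes.count)
        assert out[m].handedness == expected
    # known labels never altered; imputed count equals missing count
    for i in known:
        assert out[i].handedness == recs[i].handedness


def test_impute_all_missing_errors():
    recs = [_rec(i, 10.0 + i, handedness=None) for i in range(5)]
    with pytest.raises(CohortError):
        impute_handedness(recs, k=3)


# ---------------------------------------------------------------------------
# lattice ROIs
# ---------------------------------------------------------------------------


def test_lattice_cube_counts():
    """20 mm solid cube at 5 mm spacing holds a 4x4x4 lattice."""
    mask = np.ones((20, 20, 20), dtype=bool)
    rois = build_lattice_rois(mask, voxel_size_mm=1.0, spacing_mm=5.0)
    assert rois.n_rois == 64
    assert rois.n_voxels is not None and rois.n_voxels.sum() <= mask.sum()


def test_lattice_degenerate_single_point():
    mask = np.ones((4, 4, 4), dtype=bool)
    rois_or_err = None
    try:
        rois_or_err = build_lattice_rois(mask, 1.0, spacing_mm=10.0)
    except CohortError:
        pass
    if rois_or_err is not None:
        assert rois_or_err.n_rois == 1


def test_lattice_sphere_matches_brute_force_enumeration():
    """ROI count equals a literal triple-loop enumeration of lattice points."""
    size, radius = 30, 12.0
    origin = np.array([-15.0, -15.0, -15.0])
    idx = np.indices((size, size, size)).reshape(3, -1).T
    centers = origin + idx + 0.5
    mask = (np.linalg.norm(centers, axis=1) <= radius).reshape(size, size, size)
    rois = build_lattice_rois(mask, 1.0, spacing_mm=5.0, origin_mm=origin)

    count = 0
    for x in range(-15, 16, 5):
        for y in range(-15, 16, 5):
            for z in range(-15, 16, 5):
                i, j, k = x + 15, y + 15, z + 15
                if 0 <= i < size and 0 <= j < size and 0 <= k < size and mask[i, j, k]:
                    count += 1
    assert rois.n_rois == count


def test_lattice_translation_invariance():
    """Shifting the mask by a spacing multiple does not change the ROI count."""
    mask = np.ones((17, 23, 20), dtype=bool)
    a = build_lattice_rois(mask, 1.0, spacing_mm=5.0, origin_mm=(0, 0, 0))
    b = build_lattice_rois(mask, 1.0, spacing_mm=5.0, origin_mm=(5, 10, -5))
    assert a.n_rois == b.n_rois


def test_lattice_empty_mask_errors():
    with pytest.raises(CohortError):
        build_lattice_rois(np.zeros((5, 5, 5), dtype=bool), 1.0)


# ---------------------------------------------------------------------------
# matrix containers
# ---------------------------------------------------------------------------


def test_matrix_binary_round_trip_bit_exact(tmp_path, rng):
    v = rng.standard_normal((10, 10))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    m = AssociationMatrix("s1", v)
    path = tmp_path / "s1.fzmat"
    write_matrix(m, path)
    back = read_matrix(path)
    assert back.subject_id == "s1"
    assert np.array_equal(back.values, v)


def test_matrix_text_dialect_matches_binary(tmp_path, rng):
    v = rng.standard_normal((8, 8))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    m = AssociationMatrix("s2", v)
    write_matrix(m, tmp_path / "s2.fzmat", fmt="binary")
    write_matrix(m, tmp_path / "s2.tsv", fmt="text")
    b = read_matrix(tmp_path / "s2.fzmat")
    t = read_matrix(tmp_path / "s2.tsv")
    assert np.max(np.abs(b.values - t.values)) < 1e-15


def test_asymmetric_matrix_rejected_on_read(tmp_path):
    v = np.zeros((4, 4))
    v[0, 1] = 0.5  # not mirrored
    np.savetxt(tmp_path / "bad.tsv", v, fmt="%.17g", delimiter="\t")
    with pytest.raises(CohortError, match="asymmetric"):
        read_matrix(tmp_path / "bad.tsv")


def test_nan_offdiagonal_rejected(tmp_path):
    v = np.zeros((4, 4))
    v[0, 1] = v[1, 0] = np.nan
    raw = np.uint64(4).tobytes() + v.astype("<f8").tobytes()
    p = tmp_path / "nan.fzmat"
    p.write_bytes(raw)
    with pytest.raises(CohortError, match="non-finite"):
        read_matrix(p)


def test_non_square_text_rejected(tmp_path):
    np.savetxt(tmp_path / "rect.tsv", np.zeros((3, 4)), delimiter="\t")
    with pytest.raises(CohortError, match="non-square"):
        read_matrix(tmp_path / "rect.tsv")


def test_connection_enumeration_is_lexicographic():
    iu, ju = connection_pairs(4)
    assert list(zip(iu.tolist(), ju.tolist())) == [
        (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3),
    ]
    assert n_connections(4) == 6
    cond = np.arange(6, dtype=float)
    m = matrix_from_condensed("s", cond, 4)
    assert np.array_equal(m.condensed(), cond)


def test_roiset_requires_unique_centroids():
    with pytest.raises(CohortError, match="unique"):
        ROISet(centroids=np.array([[0, 0, 0], [0, 0, 0.0]]))
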