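"""Scan-pair applicability: geometry catalogue and content heuristics."""

import numpy as np
import pytest

import herniamech as hm
from herniamech.core import BinaryMask
from herniamech.qc import CONTENT_CHECK_IDS, GEOMETRY_CHECK_IDS, CheckStatus


def make_vol(shape=(20, 20, 10), spacing=(1, 1, 1), origin=(0, 0, 0)):
    return hm.ScanVolume(np.zeros(shape), spacing, origin)


class TestGeometry:
    def test_identical_metadata_is_applicable(self):
        rep = hm.check_pair_geometry(make_vol(), make_vol())
        assert rep.overall is hm.Applicability.APPLICABLE
        assert all(c.status is CheckStatus.PASS for c in rep.checks)

    def test_catalogue_complete_and_unique(self):
        rep = hm.check_pair_geometry(make_vol(), make_vol())
        assert sorted(c.check_id for c in rep.checks) == sorted(GEOMETRY_CHECK_IDS)

    def test_slice_count_mismatch_fails(self):
        rep = hm.check_pair_geometry(make_vol((20, 20, 120)), make_vol((20, 20, 119)))
        assert rep.check("slice_count").status is CheckStatus.FAIL
        assert rep.overall is hm.Applicability.INAPPLICABLE

    def test_slice_thickness_mismatch_fails(self):
        rep = hm.check_pair_geometry(make_vol(spacing=(1, 1, 1)), make_vol(spacing=(1, 1, 2)))
        assert rep.check("slice_thickness").status is CheckStatus.FAIL

    def test_table_reposition_fails(self):
        rep = hm.check_pair_geometry(make_vol(), make_vol(origin=(0, 0, 12.0)))
        assert rep.check("table_position").status is CheckStatus.FAIL

    @pytest.mark.parametrize(
        "other",
        [
            make_vol(),
            make_vol((20, 20, 119)),
            make_vol(spacing=(1, 1, 2)),
            make_vol(origin=(5, 0, 0)),
        ],
    )
    def test_symmetric_in_arguments(self, other):
        a = hm.check_pair_geometry(make_vol(), other)
        b = hm.check_pair_geometry(other, make_vol())
        assert [(c.check_id, c.status) for c in a.checks] == [
            (c.check_id, c.status) for c in b.checks
        ]


def ellipsoid_mask(shift=(0.0, 0.0), shape=(80, 60, 40), semi=(30, 20, 15), spacing=2.0):
    ax = [np.arange(n) * spacing - n * spacing / 2 for n in shape]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    v = ((x - shift[0]) / semi[0]) ** 2 + ((y - shift[1]) / semi[1]) ** 2 + (z / semi[2]) ** 2 <= 1
    return BinaryMask(v, np.full(3, spacing), np.array([a[0] for a in ax]))


class TestContent:
    def test_identical_masks_pass(self):
        rep = hm.check_pair_content(ellipsoid_mask(), ellipsoid_mask())
        assert rep.overall is hm.Applicability.APPLICABLE
        assert sorted(c.check_id for c in rep.checks) == sorted(CONTENT_CHECK_IDS)

    def test_translated_mask_fails_shift_with_evidence(self):
        rep = hm.check_pair_content(ellipsoid_mask(), ellipsoid_mask(shift=(20.0, 0.0)))
        chk = rep.check("shift")
        assert chk.status is CheckStatus.FAIL
        assert chk.evidence == pytest.approx(20.0, abs=2.0)

    def test_detached_component_fails_foreign_object(self):
        with_arm = ellipsoid_mask()
        with_arm.voxels[70:77, 20:40, 5:35] = True  # ~2500 voxels at 8 mm^3
        rep = hm.check_pair_content(ellipsoid_mask(), with_arm)
        assert rep.check("foreign_object").status is CheckStatus.FAIL

    def test_empty_mask_is_precondition_error(self):
        empty = ellipsoid_mask()
        empty.voxels[:] = False
        with pytest.raises(ValueError, match="non-empty"):
            hm.check_pair_content(ellipsoid_mask(), empty)

    def test_overall_inapplicable_iff_any_fail(self):
        rep = hm.check_pair_content(ellipsoid_mask(), ellipsoid_mask())
        assert rep.overall is hm.Applicability.APPLICABLE
        rep.checks[0].status = CheckStatus.WARN
        assert rep.overall is hm.Applicability.APPLICABLE  # warns never reject
        rep.checks[0].status = CheckStatus.FAIL
        assert rep.overall is hm.Applicability.INAPPLICABLE


class TestCorruptionModes:
    """Every acquisition failure mode produced by the phantom corruption
    generator must be flagged inapplicable; the clean pair must pass."""

    @staticmethod
    def qc_pair(rest, valsalva):
        rep = hm.check_pair_geometry(rest, valsalva)
        if rep.overall is hm.Applicability.INAPPLICABLE:
            return rep
        return rep.merged_with(
            hm.check_pair_content(hm.qc_content_mask(rest), hm.qc_content_mask(valsalva))
        )

    def test_clean_pair_passes(self, phantom3):
        rep = self.qc_pair(phantom3.rest_scan, phantom3.valsalva_scan)
        assert rep.overall is hm.Applicability.APPLICABLE

    @pytest.mark.parametrize(
        "mode,magnitude,expected_fail",
        [
            ("shift", 20.0, "shift"),
            ("scale", 1.15, "scale"),
            ("truncate", 40.0, "truncation"),
            ("foreign_object", 1.0, "foreign_object"),
            ("slice_mismatch", 3.0, "slice_count"),
        ],
    )
    def test_corruption_flagged_inapplicable(self, phantom3, mode, magnitude, expected_fail):
        rest, val = hm.degrade_pair(phantom3, mode, magnitude)
        rep = self.qc_pair(rest, val)
        assert rep.overall is hm.Applicability.INAPPLICABLE
        assert expected_fail in rep.failed_ids()

    @pytest.mark.parametrize("mode", ["shift", "scale", "truncate", "foreign_object", "slice_mismatch"])
    def test_zero_magnitude_is_noop(self, phantom3, mode):
        magnitude = 1.0 if mode == "scale" else 0.0
        rest, val = hm.degrade_pair(phantom3, mode, magnitude)
        assert self.qc_pair(rest, val).overall is hm.Applicability.APPLICABLE
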