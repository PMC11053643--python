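"""Biomonitoring ingest, metric normalization/grouping, plasma conversion, QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfas_bcbcr.biomonitoring import (
    DEFAULT_RB2P,
    BiomonitoringRecord,
    Matrix,
    Metric,
    MetricGroup,
    PopulationClass,
    Rb2pSource,
    group_metric,
    load_biomonitoring,
    normalize_metric,
    qc_flag,
    to_plasma,
)
from pfas_bcbcr.chem_registry import ChemicalRecord, SchemaError, ValidationError


def _rec(matrix=Matrix.SERUM, value=10.0, metric=Metric.MEAN, **kw):
    return BiomonitoringRecord(
        snaid="SNA1", dtxsid="DTXSID0000001", matrix=matrix, metric=metric,
        value=value, **kw,
    )


class TestNormalizeMetric:
    @pytest.mark.parametrize(
        "label", ["mean", "arithmetic mean", "geometric mean", "average", "Geometric Mean"]
    )
    def test_all_mean_flavors_collapse_to_mean(self, label):
        assert normalize_metric(label) is Metric.MEAN

    @pytest.mark.parametrize(
        "label,expected",
        [
            ("median", Metric.MEDIAN),
            ("50th percentile", Metric.P50),
            ("P50", Metric.P50),
            ("95th percentile", Metric.P95),
            ("maximum", Metric.MAXIMUM),
            ("min", Metric.MINIMUM),
        ],
    )
    def test_percentile_and_extreme_spellings(self, label, expected):
        assert normalize_metric(label) is expected

    def test_unknown_label_rejected_with_label_in_message(self):
        with pytest.raises(ValidationError, match="mode"):
            normalize_metric("mode")

    def test_empty_label_rejected(self):
        with pytest.raises(ValidationError):
            normalize_metric("  ")


class TestGroupMetric:
    def test_grouping_is_total_over_the_metric_enum(self):
        for m in Metric:
            assert isinstance(group_metric(m), MetricGroup)

    @pytest.mark.parametrize(
        "metric,group",
        [
            (Metric.P95, MetricGroup.HIGH),
            (Metric.MAXIMUM, MetricGroup.HIGH),
            (Metric.P75, MetricGroup.P75),
            (Metric.MEAN, MetricGroup.P50),
            (Metric.MEDIAN, MetricGroup.P50),
            (Metric.P50, MetricGroup.P50),
            (Metric.P25, MetricGroup.P25),
            (Metric.MINIMUM, MetricGroup.LOW),
            (Metric.P10, MetricGroup.LOW),
        ],
    )
    def test_band_assignment(self, metric, group):
        assert group_metric(metric) is group


class TestToPlasma:
    def test_serum_passes_through_with_factor_1(self):
        out = to_plasma(_rec(Matrix.SERUM, 7.3))
        assert out.plasma_value == 7.3
        assert out.conversion_factor == 1.0

    @pytest.mark.parametrize("matrix", [Matrix.PLASMA, Matrix.CORD_SERUM, Matrix.CORD_PLASMA])
    def test_plasma_like_matrices_are_identity(self, matrix):
        out = to_plasma(_rec(matrix, 5.5))
        assert out.plasma_value == 5.5

    def test_whole_blood_without_rb2p_uses_default_half(self):
        out = to_plasma(_rec(Matrix.WHOLE_BLOOD, 10.0), chemical=None)
        assert out.plasma_value == pytest.approx(10.0 / DEFAULT_RB2P)  # = 20
        assert out.rb2p_source is Rb2pSource.DEFAULT

    def test_cord_blood_treated_as_whole_blood(self):
        chem = ChemicalRecord("DTXSID0000001", "1", "x", "X", rb2p_predicted=0.5)
        out = to_plasma(_rec(Matrix.CORD_BLOOD, 5.0), chem)
        assert out.plasma_value == pytest.approx(10.0)
        assert out.rb2p_source is Rb2pSource.IN_VITRO_PREDICTED

    def test_blood_spot_treated_as_whole_blood(self):
        out = to_plasma(_rec(Matrix.BLOOD_SPOT, 3.0))
        assert out.conversion_factor == pytest.approx(1 / DEFAULT_RB2P)

    def test_measured_rb2p_preferred_over_predicted(self):
        chem = ChemicalRecord("DTXSID0000001", "1", "x", "X",
                              rb2p_predicted=0.5, rb2p_measured=0.8)
        out = to_plasma(_rec(Matrix.WHOLE_BLOOD, 8.0), chem)
        assert out.plasma_value == pytest.approx(10.0)
        assert out.rb2p_source is Rb2pSource.MEASURED_IN_VIVO

    def test_nonpositive_default_rb2p_rejected(self):
        with pytest.raises(ValidationError):
            to_plasma(_rec(Matrix.WHOLE_BLOOD, 1.0), default_rb2p=0.0)

    @settings(deadline=None, derandomize=True)
    @given(
        v=st.floats(min_value=0, max_value=1e6, allow_nan=False),
        k=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False),
        rb2p=st.floats(min_value=0.05, max_value=1.0),
    )
    def test_linearity_and_monotonicity(self, v, k, rb2p):
        chem = ChemicalRecord("DTXSID0000001", "1", "x", "X", rb2p_predicted=rb2p)
        base = to_plasma(_rec(Matrix.WHOLE_BLOOD, v), chem).plasma_value
        scaled = to_plasma(_rec(Matrix.WHOLE_BLOOD, k * v), chem).plasma_value
        assert scaled == pytest.approx(k * base, rel=1e-12)
        # rb2p in (0, 1] never decreases a whole-blood value
        assert base >= v


class TestQcFlag:
    def test_strict_threshold(self):
        records = [to_plasma(_rec(Matrix.SERUM, v)) for v in (50.0, 100.0, 150.0)]
        flagged = qc_flag(records, threshold=100.0)
        assert [r.plasma_value for r in flagged] == [150.0]
        assert all(f.qc_flagged for f in flagged)
        # originals untouched, nothing dropped
        assert len(records) == 3 and not any(r.qc_flagged for r in records)

    def test_empty_input_empty_output(self):
        assert qc_flag([]) == []

    def test_matches_bruteforce_filter_on_lognormal_sample(self):
        rng = np.random.default_rng(42)
        values = rng.lognormal(mean=np.log(40), sigma=1.2, size=1000)
        records = [to_plasma(_rec(Matrix.SERUM, float(v))) for v in values]
        flagged = qc_flag(records, threshold=100.0)
        assert len(flagged) == int((values > 100.0).sum())

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            qc_flag([], threshold=0)


class TestIngest:
    def _write(self, tmp_path, body, header=None):
        header = header or ("snaid,dtxsid,location,cohort,population_class,"
                            "matrix,metric,value,unit,lod,loq,n_subjects")
        p = tmp_path / "bio.csv"
        p.write_text(header + "\n" + body)
        return p

    def test_units_normalized_to_ngml(self, tmp_path):
        p = self._write(
            tmp_path,
            "S1,D1,,,general,serum,mean,5,ng/mL,,,\n"
            "S1,D1,,,general,serum,mean,5,ug/L,,,\n"
            "S1,D1,,,general,serum,mean,5,ug/mL,,,\n",
        )
        vals = [r.value for r in load_biomonitoring(p)]
        assert vals == [5.0, 5.0, 5000.0]

    def test_metric_labels_normalized_at_ingest(self, tmp_path):
        p = self._write(tmp_path, "S1,D1,,,exposed,serum,geometric mean,5,ng/mL,,,\n")
        (rec,) = load_biomonitoring(p)
        assert rec.metric is Metric.MEAN
        assert rec.population_class is PopulationClass.EXPOSED

    def test_nonnumeric_censored_value_rejected_with_warning(self, tmp_path):
        p = self._write(
            tmp_path,
            "S1,D1,,,general,serum,mean,<LOD,ng/mL,,,\n"
            "S1,D1,,,general,serum,mean,3,ng/mL,,,\n",
        )
        with pytest.warns(UserWarning, match="<LOD"):
            records = load_biomonitoring(p)
        assert len(records) == 1

    def test_missing_population_class_defaults_to_general(self, tmp_path):
        p = self._write(tmp_path, "S1,D1,,,,serum,mean,5,ng/mL,,,\n")
        (rec,) = load_biomonitoring(p)
        assert rec.population_class is PopulationClass.GENERAL

    def test_missing_required_column_is_schema_error(self, tmp_path):
        p = self._write(tmp_path, "S1,D1,serum,mean\n", header="snaid,dtxsid,matrix,metric")
        with pytest.raises(SchemaError, match="value"):
            load_biomonitoring(p)

    def test_unknown_unit_rejected(self, tmp_path):
        p = self._write(tmp_path, "S1,D1,,,general,serum,mean,5,mol/L,,,\n")
        with pytest.raises(ValidationError, match="(?i)mol/l"):
            load_biomonitoring(p)
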