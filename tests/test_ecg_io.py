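import json

import numpy as np
import pytest

from coromix.ecg_io import (
    CLASS_NAMES,
    LEAD_NAMES,
    BadSamplingRateError,
    ECGRecord,
    LengthMismatchError,
    MissingLeadError,
    class_index,
    class_name,
    read_record,
    validate_record,
    write_record,
)


def _random_record(rng, n=200, record_id="r", label="RCA"):
    leads = {name: rng.uniform(-20, 20, n) for name in LEAD_NAMES}
    return ECGRecord(record_id=record_id, fs=500.0, leads=leads, label=label)


class TestClassLabels:
    def test_name_index_bijection(self):
        for i, name in enumerate(CLASS_NAMES):
            assert class_index(name) == i
            assert class_name(i) == name

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            class_index("LCX")


class TestRecordValidation:
    def test_missing_lead_named(self, rng):
        leads = {name: rng.normal(size=10) for name in LEAD_NAMES if name != "V6"}
        with pytest.raises(MissingLeadError, match="missing-lead: V6"):
            ECGRecord(record_id="x", fs=500, leads=leads)

    def test_ragged_lengths_rejected(self, rng):
        leads = {name: rng.normal(size=10) for name in LEAD_NAMES}
        leads["V3"] = rng.normal(size=11)
        with pytest.raises(LengthMismatchError):
            ECGRecord(record_id="x", fs=500, leads=leads)

    def test_bad_sampling_rate(self, rng):
        leads = {name: rng.normal(size=10) for name in LEAD_NAMES}
        with pytest.raises(BadSamplingRateError):
            ECGRecord(record_id="x", fs=-1, leads=leads)

    def test_nonstandard_rate_warns(self, rng):
        leads = {name: rng.normal(size=10) for name in LEAD_NAMES}
        with pytest.warns(UserWarning, match="non-standard"):
            ECGRecord(record_id="x", fs=250, leads=leads)

    def test_clean_synthetic_record_has_no_issues(self, rca_record_clean):
        assert validate_record(rca_record_clean) == []

    def test_nan_sample_reported(self, random_record):
        random_record.leads["V2"][5] = np.nan
        issues = validate_record(random_record)
        assert any(i.kind == "nan-sample" and i.lead == "V2" for i in issues)

    def test_flat_lead_reported(self, random_record):
        random_record.leads["III"][:] = 0.7
        issues = validate_record(random_record)
        assert any(i.kind == "flat-lead" and i.lead == "III" for i in issues)

    def test_amplitude_bound(self, random_record):
        random_record.leads["V5"][0] = 30.0
        issues = validate_record(random_record)
        assert any(i.kind == "amplitude" and i.lead == "V5" for i in issues)


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["csv", "xml"])
    def test_roundtrip_identity(self, tmp_path, rng, fmt):
        """read(write(r)) equals r to 1e-9 mV per sample, for random records."""
        for trial in range(5):
            rec = _random_record(rng, n=50 + trial, record_id=f"t{trial}",
                                 label=CLASS_NAMES[trial % 7])
            path = write_record(rec, tmp_path / f"t{trial}.{fmt}", format=fmt)
            back = read_record(path)
            assert back.fs == rec.fs
            assert back.label == rec.label
            assert back.record_id == rec.record_id
            for name in LEAD_NAMES:
                np.testing.assert_allclose(
                    back.leads[name], rec.leads[name], rtol=0, atol=1e-9
                )

    def test_csv_shape_and_label_serialization(self, tmp_path):
        rec = ECGRecord(
            record_id="z", fs=500,
            leads={name: np.zeros(10) for name in LEAD_NAMES}, label="RCA",
        )
        path = write_record(rec, tmp_path / "z.csv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 11  # header + 10 data rows
        assert lines[0].split(",") == ["time", *LEAD_NAMES]
        sidecar = json.loads((tmp_path / "z.meta.json").read_text())
        assert sidecar["label"] == "RCA"

    def test_xml_label_attribute(self, tmp_path, rca_record_clean):
        path = write_record(rca_record_clean, tmp_path / "r.xml")
        assert 'label="RCA"' in path.read_text()


class TestDialectDetails:
    def test_csv_column_order_normalized(self, tmp_path, random_record):
        """Shuffling file columns must not change the in-memory record."""
        path = write_record(random_record, tmp_path / "a.csv")
        lines = path.read_text().splitlines()
        header = lines[0].split(",")
        perm = [0] + [12, 3, 7, 1, 2, 4, 5, 6, 8, 9, 10, 11][::-1]
        shuffled = [",".join(header[i] for i in perm)]
        for line in lines[1:]:
            vals = line.split(",")
            shuffled.append(",".join(vals[i] for i in perm))
        (tmp_path / "b.csv").write_text("\n".join(shuffled))
        (tmp_path / "b.meta.json").write_text(
            (tmp_path / "a.meta.json").read_text()
        )
        a, b = read_record(tmp_path / "a.csv"), read_record(tmp_path / "b.csv")
        assert list(a.leads) == list(LEAD_NAMES) == list(b.leads)
        for name in LEAD_NAMES:
            np.testing.assert_allclose(a.leads[name], b.leads[name], atol=1e-9)

    def test_csv_missing_lead_error(self, tmp_path, random_record):
        path = write_record(random_record, tmp_path / "a.csv")
        lines = path.read_text().splitlines()
        cut = [",".join(l.split(",")[:-1]) for l in lines]  # drop V6
        (tmp_path / "c.csv").write_text("\n".join(cut))
        (tmp_path / "c.meta.json").write_text(json.dumps({"fs": 500}))
        with pytest.raises(MissingLeadError, match="V6"):
            read_record(tmp_path / "c.csv")

    def test_csv_missing_fs_is_bad_rate(self, tmp_path, random_record):
        path = write_record(random_record, tmp_path / "a.csv")
        (tmp_path / "a.meta.json").write_text(json.dumps({"label": "RCA"}))
        with pytest.raises(BadSamplingRateError):
            read_record(path)

    def test_xml_microvolt_unit_converted(self, tmp_path):
        body = "".join(
            f'<lead name="{n}" unit="uV">1000 2000</lead>' for n in LEAD_NAMES
        )
        p = tmp_path / "u.xml"
        p.write_text(f'<ecg fs="500" id="u">{body}</ecg>')
        rec = read_record(p)
        np.testing.assert_allclose(rec.leads["I"], [1.0, 2.0])

    def test_xml_ragged_lengths_rejected(self, tmp_path):
        body = "".join(
            f'<lead name="{n}" unit="mV">{"1 2" if n != "V4" else "1 2 3"}</lead>'
            for n in LEAD_NAMES
        )
        p = tmp_path / "r.xml"
        p.write_text(f'<ecg fs="500" id="r">{body}</ecg>')
        with pytest.raises(LengthMismatchError):
            read_record(p)
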