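"""Format readers/writers and the EIC primitive."""

import numpy as np
import pandas as pd
import pytest

from isotrace.raw_io import (
    FeatureRecord,
    FormatError,
    RawRun,
    Scan,
    SchemaError,
    ValidationError,
    extract_eic,
    extract_eics_multi,
    mz_tolerance,
    read_annotation_table,
    read_feature_table,
    read_mid_table,
    read_raw_run,
    write_feature_table,
    write_mid_table,
    write_mzml,
)


def _toy_run(n_scans=3):
    scans = [
        Scan(rt=10.0 * (i + 1),
             mz=np.array([100.0, 200.0, 300.0]),
             intensity=np.array([1000.0, 2000.0, 500.0 + i]))
        for i in range(n_scans)
    ]
    return RawRun(run_id="toy", polarity="negative", scans=scans)


class TestRawRunIO:
    def test_mzml_round_trip(self, tmp_path):
        run = _toy_run()
        path = str(tmp_path / "toy.mzML")
        write_mzml(run, path)
        back = read_raw_run(path)
        assert len(back.scans) == 3
        assert back.polarity == "negative"
        np.testing.assert_allclose(back.rt, [10.0, 20.0, 30.0])
        np.testing.assert_allclose(back.scans[0].mz, run.scans[0].mz)
        np.testing.assert_allclose(back.scans[2].intensity, run.scans[2].intensity)

    def test_ms2_scans_filtered(self, tmp_path):
        run = _toy_run()
        path = str(tmp_path / "mixed.mzML")
        write_mzml(run, path)
        text = open(path).read()
        # turn the middle spectrum into an MS2 scan
        text = text.replace('name="ms level" value="1"', 'name="ms level" value="2"', 2)
        text = text.replace('name="ms level" value="2"', 'name="ms level" value="1"', 1)
        open(path, "w").write(text)
        back = read_raw_run(path)
        assert len(back.scans) == 2

    def test_zero_byte_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.mzML"
        path.write_text("")
        with pytest.raises(FormatError):
            read_raw_run(str(path))

    def test_no_ms1_scans_is_error(self, tmp_path):
        run = _toy_run(1)
        path = str(tmp_path / "ms2only.mzML")
        write_mzml(run, path)
        text = open(path).read().replace('name="ms level" value="1"',
                                         'name="ms level" value="2"')
        open(path, "w").write(text)
        with pytest.raises(FormatError):
            read_raw_run(path)


class TestEIC:
    def test_tolerance_rule(self):
        assert mz_tolerance(300.0) == pytest.approx(0.01)
        assert mz_tolerance(800.0) == pytest.approx(0.02)
        assert mz_tolerance(399.999) == pytest.approx(0.01)

    def test_single_centroid_hit(self):
        run = _toy_run()
        eic = extract_eic(run, 200.0, (0.0, 100.0))
        np.testing.assert_allclose(eic.intensity, [2000.0, 2000.0, 2000.0])
        eic = extract_eic(run, 200.5, (0.0, 100.0))
        np.testing.assert_allclose(eic.intensity, [0.0, 0.0, 0.0])

    def test_empty_window_gives_empty_eic(self):
        eic = extract_eic(_toy_run(), 200.0, (500.0, 600.0))
        assert len(eic) == 0

    def test_additivity_over_scan_subsets(self):
        """EIC of a run equals the concatenation over disjoint scan subsets."""
        run = _toy_run(6)
        whole = extract_eic(run, 100.0, (0.0, 1000.0))
        first = extract_eic(run, 100.0, (0.0, 30.0))
        second = extract_eic(run, 100.0, (30.1, 1000.0))
        np.testing.assert_allclose(
            np.concatenate([first.intensity, second.intensity]), whole.intensity)

    def test_centroid_order_invariance(self):
        rt = 10.0
        mz = np.array([199.995, 200.001, 200.005])
        inten = np.array([10.0, 20.0, 30.0])
        a = RawRun("a", "negative", [Scan(rt, mz, inten)])
        perm = [2, 0, 1]
        b = RawRun("b", "negative", [Scan(rt, mz[perm], inten[perm])])
        b.scans[0].mz, b.scans[0].intensity = mz, inten  # reader sorts; emulate
        ea = extract_eic(a, 200.0, (0.0, 20.0))
        eb = extract_eic(b, 200.0, (0.0, 20.0))
        assert ea.intensity[0] == eb.intensity[0] == 60.0

    def test_multi_channel_matches_single(self):
        run = _toy_run(5)
        multi = extract_eics_multi(run, [100.0, 300.0], (0.0, 1000.0))
        for mz, eic in zip([100.0, 300.0], multi):
            single = extract_eic(run, mz, (0.0, 1000.0))
            np.testing.assert_allclose(eic.intensity, single.intensity)


class TestAnnotationTable:
    def _write(self, tmp_path, rows, header=None):
        header = header or "metabolite_id,name,formula,adduct,mz,rt,msi_level,feature_id"
        path = tmp_path / "ann.csv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return str(path)

    def test_parse_row(self, tmp_path):
        path = self._write(tmp_path, ["glc,glucose,C6H12O6,[M-H]-,179.0561,485,1,F0001"])
        recs = read_annotation_table(path)
        assert len(recs) == 1
        assert recs[0].formula == "C6H12O6"
        assert recs[0].rt == 485.0

    def test_unreliable_adduct_rejected(self, tmp_path):
        path = self._write(tmp_path, [
            "glc,glucose,C6H12O6,[M-H]-,179.0561,485,1,F0001",
            "x,acn-adduct,C6H12O6,[M+ACN+H]+,222.1,300,2,F0002",
        ])
        recs = read_annotation_table(path)
        assert [r.metabolite_id for r in recs] == ["glc"]

    def test_bad_formula_rejected(self, tmp_path):
        path = self._write(tmp_path, ["x,bad,Xx9,[M-H]-,100.0,300,2,F0002"])
        assert read_annotation_table(path) == []

    def test_missing_column_is_schema_error(self, tmp_path):
        path = self._write(
            tmp_path, ["glc,glucose,[M-H]-,179.0561,485,1,F0001"],
            header="metabolite_id,name,adduct,mz,rt,msi_level,feature_id")
        with pytest.raises(SchemaError):
            read_annotation_table(path)


class TestFeatureTable:
    def test_round_trip(self, tmp_path):
        recs = [
            FeatureRecord("F1", 179.0561, 485.0, 470.0, 500.0, {"u1": 1e4, "u2": 2e4}),
            FeatureRecord("F2", 87.0088, 300.0, 290.0, 310.0, {"u1": 5e3, "u2": 0.0}),
        ]
        path = str(tmp_path / "feat.csv")
        write_feature_table(recs, path)
        back = read_feature_table(path)
        assert len(back) == 2
        assert back[0].per_sample_height == {"u1": 1e4, "u2": 2e4}

    def test_duplicate_feature_id(self, tmp_path):
        path = tmp_path / "feat.csv"
        path.write_text("feature_id,mz,rt_apex,rt_min,rt_max\n"
                        "F1,100,50,40,60\nF1,200,70,60,80\n")
        with pytest.raises(ValidationError):
            read_feature_table(str(path))

    def test_inverted_bounds(self, tmp_path):
        path = tmp_path / "feat.csv"
        path.write_text("feature_id,mz,rt_apex,rt_min,rt_max\nF1,100,195,200,190\n")
        with pytest.raises(ValidationError):
            read_feature_table(str(path))


class TestMIDTable:
    def _frame(self):
        rows = []
        for run in ("a", "b"):
            for i, f in enumerate((0.25, 0.25, 0.5)):
                rows.append({"metabolite_id": "m1", "isotopologue_index": i,
                             "run_id": run, "group": "t24h",
                             "corrected_intensity": 1e4 * f, "labeled_fraction": f})
        return pd.DataFrame(rows)

    def test_round_trip_identity(self, tmp_path):
        df = self._frame()
        df.loc[0, "labeled_fraction"] = 0.123456789012345
        path = str(tmp_path / "mid.csv")
        write_mid_table(df, path)
        back = read_mid_table(path)
        np.testing.assert_allclose(back["labeled_fraction"], df["labeled_fraction"],
                                   atol=1e-12)
        np.testing.assert_allclose(back["corrected_intensity"], df["corrected_intensity"],
                                   rtol=1e-12)

    def test_fraction_out_of_range_rejected(self, tmp_path):
        df = self._frame()
        df.loc[0, "labeled_fraction"] = 1.2
        with pytest.raises(ValidationError):
            write_mid_table(df, str(tmp_path / "mid.csv"))


class TestMzXML:
    def test_read_mzxml(self, tmp_path):
        import base64
        import struct

        peaks = base64.b64encode(
            struct.pack(">4f", 100.0, 1000.0, 200.0, 2000.0)).decode()
        doc = (
            '<?xml version="1.0" encoding="ISO-8859-1"?>\n'
            '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">\n'
            ' <msRun scanCount="1">\n'
            '  <scan num="1" msLevel="1" peaksCount="2" polarity="-"'
            ' retentionTime="PT10.0S" centroided="1">\n'
            '   <peaks compressionType="none" compressedLen="0" precision="32"'
            f' byteOrder="network" contentType="m/z-int">{peaks}</peaks>\n'
            "  </scan>\n </msRun>\n</mzXML>\n"
        )
        path = tmp_path / "toy.mzXML"
        path.write_text(doc)
        run = read_raw_run(str(path))
        assert run.polarity == "negative"
        assert len(run.scans) == 1
        assert run.scans[0].rt == pytest.approx(10.0)
        np.testing.assert_allclose(run.scans[0].mz, [100.0, 200.0])
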