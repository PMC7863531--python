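import numpy as np
import pytest

import shelterops as so


@pytest.fixture(scope="session")
def breed_size_map():
    return so.load_breed_size_map()


@pytest.fixture(scope="session")
def color_synonyms():
    return so.load_color_synonyms()


@pytest.fixture(scope="session")
def clean_records():
    """Small clean synthetic batch shared across tests."""
    cfg = so.GeneratorConfig(n_records=600, seed=11, error_rate=0.0)
    return so.generate_records(cfg)


@pytest.fixture(scope="session")
def processed_records(clean_records):
    processed, report = so.process_records(clean_records, strategy="remove_rows")
    assert report.n_removed == 0
    return processed


@pytest.fixture(scope="session")
def encoded(processed_records):
    manifest = so.build_manifest(processed_records)
    X = so.encode_features(processed_records, manifest)
    y = so.target_vector(processed_records)
    return manifest, X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def write_raw_csv(path, rows, header=None):
    """Write a raw-dialect CSV from a list of row dicts (missing keys blank)."""
    cols = header or list(so.records.RAW_COLUMNS)
    lines = [",".join(cols)]
    for row in rows:
        lines.append(",".join(str(row.get(c, "")) for c in cols))
    path.write_text("\n".join(lines) + "\n")
    return path
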