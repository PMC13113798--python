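import pytest

from storyload import (
    fixture_gain_records,
    fixture_roles,
    load_fixtures,
    profile_features,
    table1_feature_vectors,
)


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def table1_vectors(fixtures):
    return table1_feature_vectors(fixtures)


@pytest.fixture(scope="session")
def study_profile(fixtures, table1_vectors):
    """Profile of the 12 published stimuli rebuilt from raw features."""
    return profile_features(table1_vectors, roles=fixture_roles(fixtures))


@pytest.fixture(scope="session")
def study_gains(fixtures):
    return fixture_gain_records(fixtures)


@pytest.fixture
def make_corpus(tmp_path):
    """Write (id, text, role[, override]) tuples as texts + manifest."""

    def _make(rows):
        lines = ["id,file,role,sentence_count_override"]
        for row in rows:
            sid, text, role = row[0], row[1], row[2]
            override = row[3] if len(row) > 3 else ""
            fname = f"{sid}.txt"
            (tmp_path / fname).write_text(text, encoding="utf-8")
            lines.append(f"{sid},{fname},{role},{override}")
        manifest = tmp_path / "manifest.csv"
        manifest.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return manifest

    return _make
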