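"""Dialect parsers and the standardized TSV round trip."""

import pytest
from hypothesis import given, settings, strategies as st

import ppipath as pp
from ppipath.formats import FormatError, StandardRow, StandardTable


# -- PINA / iRefIndex dialects ----------------------------------------------


def test_parse_pina_extracts_fields(tmp_path):
    path = tmp_path / "pina.tsv"
    path.write_text(
        "ID(s) interactor A\tID(s) interactor B\tPublication Identifier(s)\n"
        "uniprotkb:P04637\tuniprotkb:Q13625\tpubmed:12345678\n"
    )
    result = pp.parse_pina(path)
    (rec,) = result.records
    assert (rec.id_a, rec.id_b, rec.source_db) == ("P04637", "Q13625", pp.PINA)
    assert rec.pubmed_ids == (12345678,)
    assert result.skipped == 0


def test_parse_pina_skips_malformed_lines_and_counts(tmp_path):
    path = tmp_path / "pina.tsv"
    path.write_text(
        "A\tB\tpmids\n"
        "uniprotkb:P04637\t\tpubmed:1\n"       # missing interactor B
        "uniprotkb:P04637\n"                    # too few columns
        "uniprotkb:P04637\tuniprotkb:Q13625\tpubmed:2\n"
    )
    result = pp.parse_pina(path)
    assert len(result.records) == 1
    assert result.skipped == 2


def test_parse_pina_zero_parseable_lines_is_a_format_error(tmp_path):
    path = tmp_path / "pina.tsv"
    path.write_text("A\tB\n\t\n")
    with pytest.raises(FormatError):
        pp.parse_pina(path)


def test_parse_irefindex_multiple_pubmed_ids(tmp_path):
    path = tmp_path / "iref.tsv"
    path.write_text(
        "uidA\tuidB\taltA\taltB\taliasA\taliasB\tmethod\tpmids\n"
        "uniprotkb:P1\tuniprotkb:P2\t-\t-\tGA\tGB\tpsi-mi:MI:0018"
        "\tpubmed:11111111|pubmed:22222222\n"
    )
    (rec,) = pp.parse_irefindex(path).records
    assert rec.source_db == pp.IREFINDEX
    assert rec.pubmed_ids == (11111111, 22222222)


def test_mitab_parse_counts_match_generator_bookkeeping(random_bundle):
    assert len(pp.parse_pina(random_bundle.pina_path).records) == (
        random_bundle.lines_written[pp.PINA]
    )
    assert len(pp.parse_irefindex(random_bundle.iref_path).records) == (
        random_bundle.lines_written[pp.IREFINDEX]
    )


def test_unknown_prefix_kept_verbatim():
    assert pp.formats.strip_id_prefix("uniprotkb:P04637") == "P04637"
    assert pp.formats.strip_id_prefix("refseq:NP_000537") == "NP_000537"
    assert pp.formats.strip_id_prefix("chebi:1234") == "chebi:1234"


# -- STRING dialect ---------------------------------------------------------


@pytest.fixture()
def string_files(tmp_path):
    links = tmp_path / "links.txt"
    links.write_text(
        "protein1 protein2 combined_score\n"
        "9606.ENSP1 9606.ENSP2 699\n"
        "9606.ENSP1 9606.ENSP2 700\n"
        "9606.ENSP2 9606.ENSP3 950\n"
        "9606.ENSP1 9606.ENSPX 800\n"  # no alias for ENSPX
    )
    alias = tmp_path / "alias.tsv"
    alias.write_text(
        "#string_protein_id\talias\tsource\n"
        "9606.ENSP1\tP1\tUniProt_AC\n"
        "9606.ENSP2\tP2\tUniProt_AC\n"
        "9606.ENSP3\tP3\tUniProt_AC\n"
    )
    return links, alias


def test_string_default_threshold_keeps_700_drops_699(string_files):
    links, alias = string_files
    result = pp.parse_string(links, alias)
    scores = [r.string_score for r in result.records]
    assert 700 in scores and 699 not in scores
    assert result.dropped_unaliased == 1


def test_string_threshold_zero_emits_all_aliased_rows(random_bundle):
    result = pp.parse_string(
        random_bundle.string_links_path,
        random_bundle.string_alias_path,
        score_threshold=0,
    )
    expected = random_bundle.lines_written[pp.STRING] - (
        random_bundle.decoys_written[pp.STRING]
    )
    assert len(result.records) == expected


def test_string_threshold_monotonicity(string_files):
    links, alias = string_files

    def kept(threshold):
        return {
            (r.id_a, r.id_b, r.string_score)
            for r in pp.parse_string(links, alias, score_threshold=threshold).records
        }

    low = kept(0)
    for t in (500, 700, 800, 951):
        assert kept(t) <= low
        low_t = kept(t)


def test_string_missing_alias_file_is_io_error(string_files, tmp_path):
    links, _ = string_files
    with pytest.raises(OSError):
        pp.parse_string(links, tmp_path / "nope.tsv")


# -- RawRecord invariants ---------------------------------------------------


def test_raw_record_invariants():
    with pytest.raises(ValueError):
        pp.RawRecord(id_a="", id_b="B", source_db=pp.PINA)
    with pytest.raises(ValueError):
        pp.RawRecord(id_a="A", id_b="B", source_db=pp.STRING)  # score required
    with pytest.raises(ValueError):
        pp.RawRecord(id_a="A", id_b="B", source_db=pp.PINA, string_score=500)
    with pytest.raises(ValueError):
        pp.RawRecord(
            id_a="A", id_b="B", source_db=pp.STRING, string_score=500,
            pubmed_ids=(1,),
        )


def test_every_parsed_record_satisfies_invariants(random_bundle):
    """Parsing a whole fixture corpus never emits an invalid record
    (RawRecord validates in its constructor)."""
    for result in (
        pp.parse_pina(random_bundle.pina_path),
        pp.parse_irefindex(random_bundle.iref_path),
        pp.parse_string(
            random_bundle.string_links_path, random_bundle.string_alias_path
        ),
    ):
        for rec in result.records:
            assert rec.id_a.strip() and rec.id_b.strip()
            assert (rec.string_score is not None) == (rec.source_db == pp.STRING)


# -- standard TSV round trip ------------------------------------------------


def test_empty_table_round_trips(tmp_path):
    path = tmp_path / "std.tsv"
    pp.write_standard(StandardTable(), path)
    assert pp.read_standard(path) == StandardTable()


def test_cost_override_round_trips(tmp_path):
    row = StandardRow(
        acc_a="A", acc_b="B", sources=frozenset({pp.PINA}), cost_override=2.5
    )
    path = tmp_path / "std.tsv"
    pp.write_standard(StandardTable(rows=[row]), path)
    assert pp.read_standard(path).rows[0].cost_override == 2.5


def test_fixture_table_write_read_write_is_byte_stable(random_bundle, tmp_path):
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    pp.write_standard(random_bundle.truth_table, p1)
    pp.write_standard(pp.read_standard(p1), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_duplicate_pair_on_read_names_the_pair(tmp_path):
    path = tmp_path / "std.tsv"
    path.write_text(
        "accA\taccB\tsources\tpmids\tstring_score\tcost\n"
        "A\tB\tPINA\t1\t\t\n"
        "A\tB\tPINA\t2\t\t\n"
    )
    with pytest.raises(FormatError, match=r"\('A', 'B'\)"):
        pp.read_standard(path)


_acc = st.text(
    alphabet=st.sampled_from("ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"),
    min_size=1,
    max_size=8,
)


@st.composite
def standard_tables(draw):
    pairs = draw(
        st.sets(st.tuples(_acc, _acc), min_size=0, max_size=12)
    )
    rows = []
    for a, b in sorted(pairs):
        a, b = min(a, b), max(a, b)
        if (a, b) in {r.pair for r in rows}:
            continue
        is_string = draw(st.booleans())
        sources = {pp.STRING} if is_string else {draw(st.sampled_from([pp.PINA, pp.IREFINDEX]))}
        rows.append(
            StandardRow(
                acc_a=a,
                acc_b=b,
                sources=frozenset(sources),
                pubmed_ids=frozenset()
                if is_string
                else frozenset(draw(st.sets(st.integers(1, 10**8), max_size=3))),
                string_score=draw(st.integers(1, 999)) if is_string else None,
                cost_override=draw(
                    st.one_of(st.none(), st.floats(1, 10, allow_nan=False))
                ),
            )
        )
    return StandardTable(rows=rows)


@settings(max_examples=50, deadline=None)
@given(table=standard_tables())
def test_standard_round_trip_identity_property(table, tmp_path_factory):
    path = tmp_path_factory.mktemp("rt") / "std.tsv"
    pp.write_standard(table, path)
    assert pp.read_standard(path) == table
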