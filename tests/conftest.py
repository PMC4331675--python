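import pytest

import ppipath as pp


def run_pipeline(bundle, string_threshold=pp.DEFAULT_STRING_THRESHOLD):
    """Parse -> map -> combine over a fixture bundle's files.

    Only dialect files the generator actually populated are parsed.
    """
    mapping = pp.build_mapping(bundle.mapping_path)
    sets = []
    if bundle.lines_written[pp.PINA]:
        sets.append(pp.canonicalize(pp.parse_pina(bundle.pina_path).records, mapping))
    if bundle.lines_written[pp.IREFINDEX]:
        sets.append(
            pp.canonicalize(pp.parse_irefindex(bundle.iref_path).records, mapping)
        )
    if bundle.lines_written[pp.STRING]:
        sets.append(
            pp.canonicalize(
                pp.parse_string(
                    bundle.string_links_path,
                    bundle.string_alias_path,
                    score_threshold=string_threshold,
                ).records,
                mapping,
            )
        )
    table, overlaps = pp.combine(sets)
    return mapping, table, overlaps, pp.PPIGraph.from_table(table)


@pytest.fixture(scope="session")
def random_bundle(tmp_path_factory):
    return pp.gen_random_ppi(
        50, 120, seed=42, out_dir=tmp_path_factory.mktemp("random")
    )


@pytest.fixture(scope="session")
def hub150(tmp_path_factory):
    return pp.gen_hub(150, seed=3, out_dir=tmp_path_factory.mktemp("hub150"))


@pytest.fixture(scope="session")
def layered_1321(tmp_path_factory):
    return pp.gen_path_graph([1, 3, 2, 1], seed=5, out_dir=tmp_path_factory.mktemp("l"))


@pytest.fixture()
def mapping_rows(tmp_path):
    path = tmp_path / "mapping.tsv"
    path.write_text(
        "accession\treviewed\tgene_name\tsynonyms\tsecondary_accessions\n"
        "P04637\treviewed\tTP53\tp53;LFS1\tQ15086\n"
        "Q13625\treviewed\tTP53BP2\tASPP2\t\n"
        "A00001\tunreviewed\tDUPGENE\t\t\n"
        "B00002\treviewed\tDUPGENE\t\t\n"
        "C00003\treviewed\tTWINA\t\t\n"
        "C00001\treviewed\tTWINA\t\t\n"
    )
    return path
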