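"""Fusion: header enrichment, structured comments, packaging, atomicity."""

import io
import zipfile

import pytest

from mixsfuse.cd_model import CDElement, RangeAssignment, assign_ranges, CDFastaHeader
from mixsfuse.errors import (
    AlreadyEnrichedError,
    CDValidationError,
    EmptyCommentError,
    FastaError,
    RangeError,
)
from mixsfuse.fasta_stream import CollectingHandler, parse_fasta
from mixsfuse.fixtures import generate_fixture
from mixsfuse.fusion import emit_structured_comment, enrich_headers, fuse


def make_cd(registry, report_type="mimarks_s", package="water", label="s1", **over):
    values = {p.short_name: p.example for p in registry.compose_parameter_set(report_type, package)}
    values["investigation_type"] = "mimarks-survey" if report_type.startswith("mimarks") else "bacteria_archaea"
    values.update(over.pop("values", {}))
    return CDElement(report_type, package, values=values, label=label, **over)


def parse_modifiers(header_line):
    """Independent oracle for '[name=value]' source-modifier tokens."""
    import re

    return dict(re.findall(r"\[([^\s=\]]+)=([^\]]*)\]", header_line))


# --- enrich_headers ---------------------------------------------------------

def one_set_assignment(ids, label="s1"):
    return RangeAssignment(by_id={i: label for i in ids}, scenario="one_to_many")


def test_enrich_header_token_syntax():
    out = io.StringIO()
    headers = {"s1": CDFastaHeader({"lat_lon": "38.98 N 77.11 W"})}
    n = enrich_headers(io.StringIO(">s1 desc\nACGT\n"), one_set_assignment(["s1"]), headers, out)
    assert n == 1
    lines = out.getvalue().splitlines()
    assert lines[0] == ">s1 desc [lat_lon=38.98 N 77.11 W]"
    assert lines[1] == "ACGT"
    assert parse_modifiers(lines[0]) == {"lat_lon": "38.98 N 77.11 W"}


def test_enrich_with_empty_qualifiers_keeps_header():
    out = io.StringIO()
    headers = {"s1": CDFastaHeader({})}
    n = enrich_headers(io.StringIO(">s1 desc\nACGT\n"), one_set_assignment(["s1"]), headers, out)
    assert n == 1
    assert out.getvalue().splitlines()[0] == ">s1 desc"


def test_enrich_refuses_pre_enriched_input():
    headers = {"s1": CDFastaHeader({"host": "Homo sapiens"})}
    with pytest.raises(AlreadyEnrichedError, match="s1"):
        enrich_headers(
            io.StringIO(">s1 [lat_lon=1 N 1 E]\nACGT\n"),
            one_set_assignment(["s1"]), headers, io.StringIO(),
        )


def test_enrich_unassigned_id_is_range_gap():
    with pytest.raises(RangeError) as exc:
        enrich_headers(io.StringIO(">ghost\nACGT\n"), one_set_assignment(["s1"]),
                       {"s1": CDFastaHeader({})}, io.StringIO())
    assert exc.value.code == "RANGE_GAP"


def test_enrich_rewraps_but_preserves_residues():
    seq = "ACGT" * 53  # 212 residues, not a multiple of the wrap width
    out = io.StringIO()
    enrich_headers(io.StringIO(f">s1\n{seq}\n"), one_set_assignment(["s1"]),
                   {"s1": CDFastaHeader({})}, out, wrap=70)
    body = out.getvalue().splitlines()[1:]
    assert all(len(line) <= 70 for line in body)
    assert "".join(body) == seq


# --- emit_structured_comment ------------------------------------------------

def test_structured_comment_framing(registry):
    element = CDElement("mimarks_s", "water",
                        values={"depth": "10 m", "temp": "14.8 C"}, label="x")
    sink = io.StringIO()
    block = emit_structured_comment(element, registry, sink)
    lines = sink.getvalue().splitlines()
    assert len(lines) == 4
    assert lines[0] == "StructuredCommentPrefix\tMIMARKS-Data"
    assert lines[-1] == "StructuredCommentSuffix\tMIMARKS-Data"
    assert block.rows == [("depth", "10 m"), ("temp", "14.8 C")]


def test_structured_comment_sanitizes_tabs(registry):
    element = CDElement("mimarks_s", "water", values={"samp_collect_device": "a\tb"})
    sink = io.StringIO()
    with pytest.warns(UserWarning, match="tab"):
        block = emit_structured_comment(element, registry, sink)
    assert block.rows == [("samp_collect_device", "a b")]


def test_structured_comment_write_then_parse_oracle(registry):
    """An independent .cmt reader recovers exactly the (name, value) pairs."""
    element = make_cd(registry)
    sink = io.StringIO()
    block = emit_structured_comment(element, registry, sink)
    lines = sink.getvalue().splitlines()
    parsed = [tuple(line.split("\t", 1)) for line in lines]
    assert parsed[0] == ("StructuredCommentPrefix", block.prefix_name)
    assert parsed[-1] == ("StructuredCommentSuffix", block.prefix_name)
    assert parsed[1:-1] == block.rows
    assert all(len(pair) == 2 for pair in parsed)


def test_structured_comment_refuses_empty(registry):
    element = CDElement("mimarks_s", "water", values={"lat_lon": "1 N 1 E"})
    with pytest.raises(EmptyCommentError):
        emit_structured_comment(element, registry, io.StringIO())


def test_structured_comment_full_names(registry):
    element = CDElement("mimarks_s", "water", values={"depth": "10 m"})
    block = emit_structured_comment(element, registry, io.StringIO(), field_names="full")
    assert block.rows == [("depth", "10 m")] or block.rows[0][0] == "depth"
    full = emit_structured_comment(element, registry, io.StringIO(), field_names="full")
    assert full.rows[0][0] == registry.parameter_info("depth").full_name


# --- fuse -------------------------------------------------------------------

def test_fuse_single_sequence_one_cd_set(registry, tmp_path):
    info = generate_fixture("single", 7, tmp_path / "fix", registry=registry)
    manifest = fuse(info.fasta, info.cd_sets, registry, tmp_path / "out")
    assert manifest.scenario == "one_to_one"
    assert manifest.records_enriched == manifest.records_read == 1
    assert len(manifest.comment_files) == 1
    assert manifest.archive is None
    assert manifest.comment_files[0][1].exists()


def test_fuse_genome_one_cd_set_for_all(registry, tmp_path):
    info = generate_fixture("genome", 7, tmp_path / "fix", registry=registry,
                            genome_total_size=50_000, genome_contigs=8)
    manifest = fuse(info.fasta, info.cd_sets, registry, tmp_path / "out")
    assert manifest.scenario == "one_to_many"
    assert manifest.records_enriched == 8
    assert len(manifest.comment_files) == 1 and manifest.archive is None


def test_fuse_clone_library_four_sets(registry, tmp_path):
    info = generate_fixture("clonelib", 42, tmp_path / "fix", registry=registry)
    manifest = fuse(info.fasta, info.cd_sets, registry, tmp_path / "out")
    assert manifest.scenario == "many_to_many"
    assert manifest.records_enriched == 99
    assert len(manifest.comment_files) == 4
    with zipfile.ZipFile(manifest.archive) as zf:
        assert sorted(zf.namelist()) == sorted(f"{lab}.cmt" for lab, _ in manifest.comment_files)


def test_fuse_conservation_of_cd_values(registry, qualifier_map, tmp_path):
    """Every CD value appears exactly once across header + comment."""
    info = generate_fixture("single", 3, tmp_path / "fix", registry=registry)
    manifest = fuse(info.fasta, info.cd_sets, registry, tmp_path / "out")
    header_line = manifest.enriched_fasta.read_text().splitlines()[0]
    quals = parse_modifiers(header_line)
    cmt_lines = manifest.comment_files[0][1].read_text().splitlines()[1:-1]
    comment = dict(line.split("\t", 1) for line in cmt_lines)
    inverse = {v: k for k, v in qualifier_map.items()}
    recovered = {inverse[k]: v for k, v in quals.items()}
    assert not set(recovered) & set(comment), "no field in both destinations"
    recovered.update(comment)
    assert recovered == info.cd_sets[0].values


def test_fuse_residue_integrity(registry, tmp_path):
    info = generate_fixture("clonelib", 11, tmp_path / "fix", registry=registry)
    manifest = fuse(info.fasta, info.cd_sets, registry, tmp_path / "out", wrap=53)
    before, after = CollectingHandler(), CollectingHandler()
    assert parse_fasta(str(info.fasta), before).ok
    assert parse_fasta(str(manifest.enriched_fasta), after).ok
    assert [r.residues for r in after.records] == [r.residues for r in before.records]
    assert [r.id for r in after.records] == [r.id for r in before.records]


def test_fuse_is_not_idempotent_by_design(registry, tmp_path):
    """Re-running fusion on its own output must refuse double annotation."""
    info = generate_fixture("single", 5, tmp_path / "fix", registry=registry)
    manifest = fuse(info.fasta, info.cd_sets, registry, tmp_path / "out")
    with pytest.raises(AlreadyEnrichedError):
        fuse(manifest.enriched_fasta, info.cd_sets, registry, tmp_path / "out2")
    assert not (tmp_path / "out2").exists()


def test_fuse_all_or_nothing_on_bad_cd(registry, tmp_path):
    info = generate_fixture("single", 5, tmp_path / "fix", registry=registry)
    info.cd_sets[0].values["lat_lon"] = "not a position"
    out = tmp_path / "out"
    with pytest.raises(CDValidationError):
        fuse(info.fasta, info.cd_sets, registry, out)
    assert not out.exists()


def test_fuse_all_or_nothing_on_bad_fasta(registry, tmp_path):
    info = generate_fixture("single", 5, tmp_path / "fix", registry=registry)
    bad_fasta = tmp_path / "bad.fasta"
    bad_fasta.write_text(">a\nACGT\n>a\nGGGG\n")
    out = tmp_path / "out"
    with pytest.raises(FastaError):
        fuse(bad_fasta, info.cd_sets, registry, out)
    assert not out.exists()


def test_fuse_lenient_downgrades_violations(registry, tmp_path):
    info = generate_fixture("single", 5, tmp_path / "fix", registry=registry)
    info.cd_sets[0].values["lat_lon"] = "not a position"
    with pytest.warns(UserWarning, match="SYNTAX"):
        manifest = fuse(info.fasta, info.cd_sets, registry, tmp_path / "out", strict=False)
    assert manifest.records_enriched == 1


def test_fuse_assignment_matches_generator_partition(registry, tmp_path):
    info = generate_fixture("clonelib", 42, tmp_path / "fix", registry=registry)
    assignment = assign_ranges(info.cd_sets, info.ids)
    for label, first, last in info.partition:
        lo, hi = info.ids.index(first), info.ids.index(last)
        assert assignment.counts[label] == hi - lo + 1
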