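import random

import pytest
from hypothesis import HealthCheck, settings

from mixsfuse import load_registry
from mixsfuse.fasta_stream import ParseHandler

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def qualifier_map():
    from mixsfuse import load_qualifier_map

    return load_qualifier_map()


class ProbeHandler(ParseHandler):
    """Asserts the bounded-memory contract: max chunk payload, and collects
    per-record reassembled residues for oracle comparison."""

    def __init__(self, keep_residues=True):
        self.keep_residues = keep_residues
        self.max_payload = 0
        self.ids = []
        self.residues = []
        self._parts = []

    def record_start(self, event):
        self.ids.append(event.payload[0])
        self._parts = []

    def sequence_chunk(self, event):
        self.max_payload = max(self.max_payload, len(event.payload))
        if self.keep_residues:
            self._parts.append(event.payload)

    def record_end(self, event):
        if self.keep_residues:
            self.residues.append("".join(self._parts))


@pytest.fixture
def probe_handler_cls():
    return ProbeHandler


def make_random_fasta(rng: random.Random, n_records: int, max_len: int = 200) -> tuple[str, list, list]:
    """Random well-formed FASTA text with mixed wrapping and line endings.

    Returns (text, ids, residues).
    """
    ids, seqs, lines = [], [], []
    eol = rng.choice(["\n", "\r\n"])
    for i in range(n_records):
        rid = f"seq_{i}_{rng.randrange(10**6)}"
        desc = rng.choice(["", "some description", "x y z"])
        seq = "".join(rng.choice("ACGTN") for _ in range(rng.randint(1, max_len)))
        ids.append(rid)
        seqs.append(seq)
        head = rid if not desc else f"{rid} {desc}"
        lines.append(f">{head}{eol}")
        width = rng.choice([17, 60, 70, 1000])
        for j in range(0, len(seq), width):
            lines.append(seq[j : j + width] + eol)
    return "".join(lines), ids, seqs
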