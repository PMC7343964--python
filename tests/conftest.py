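import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sulfenlink.digestion import ProteinRecord

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20200702)


@pytest.fixture(scope="session")
def tiny_database():
    """Hand-built proteins covering unique, shared and repeated peptides."""
    return [
        # Carries the reporter context: EGSLLR | CSEIWDR | ITTHPK
        ProteinRecord("PROBE1", "PROBE1 reporter-bearing construct", "MKEGSLLRCSEIWDRITTHPK"),
        ProteinRecord("TGT1", "TGT1 unique partner", "MGGKVIEYCKLLDDR"),
        # KLKECEK occurs in both TGT2 and TGT3 (shared-peptide ambiguity).
        ProteinRecord("TGT2", "TGT2 shared peptide", "MGGKLKECEKTTTRWWNPLK"),
        ProteinRecord("TGT3", "TGT3 shared peptide", "MPPPFFRKLKECEKSSSK"),
        # CATITPDEGR with and without a missed-cleavage extension.
        ProteinRecord("TGT4", "TGT4 missed cleavage pair", "MNNRCATITPDEGRVTEFGLKHHHK"),
    ]


def brute_force_digest(sequence, max_missed, min_len, max_len, proline_rule=True):
    """Substring-enumeration oracle for tryptic digestion.

    Enumerates every substring and keeps those whose boundaries are
    cleavage sites (or protein termini) and whose internal uncut K/R count
    is within the missed-cleavage budget.
    """
    n = len(sequence)

    def is_cut(b):  # cleavage between b-1 and b (0-based boundary offset)
        if b == 0 or b == n:
            return True
        if sequence[b - 1] not in "KR":
            return False
        return not (proline_rule and sequence[b] == "P")

    out = set()
    for i in range(n):
        for j in range(i + 1, n + 1):
            if not (is_cut(i) and is_cut(j)):
                continue
            if not min_len <= j - i <= max_len:
                continue
            missed = sum(1 for b in range(i + 1, j) if is_cut(b))
            if missed <= max_missed:
                out.add((sequence[i:j], i + 1, j, missed))
    return out
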