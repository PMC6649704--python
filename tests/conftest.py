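import numpy as np
import pytest

from irphase import CdsRecord, GeneticCode, at_rich_usage


@pytest.fixture(scope="session")
def table5():
    return GeneticCode.from_ncbi(5)


@pytest.fixture(scope="session")
def standard_code():
    return GeneticCode.from_ncbi(1)


@pytest.fixture(scope="session")
def usage_at(table5):
    return at_rich_usage(table5, at=0.72)


@pytest.fixture()
def mkf_cds():
    """Met-Lys-Phe-Gly host with the AAA/TTT loopless stem at codons 2-3."""
    return CdsRecord("sp", "g1", "ATGAAATTTGGA")


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture(scope="session")
def brute_force_perfect_irs():
    """Independent oracle: string-level enumeration of maximal perfect repeats.

    For every candidate outermost base pair (a, b) that is complementary and
    outward-maximal, pairs are consumed inward while complementarity holds and
    the arms do not meet; the resulting run is one maximal repeat.
    """
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}

    def oracle(seq: str, min_arm: int, max_loop=None):
        n = len(seq)
        found = []
        for a in range(n):
            for b in range(n - 1, a, -1):
                if comp[seq[a]] != seq[b]:
                    continue
                if a > 0 and b < n - 1 and comp[seq[a - 1]] == seq[b + 1]:
                    continue  # not outward-maximal
                i, j = a, b
                run = 0
                while i < j and comp[seq[i]] == seq[j]:
                    run += 1
                    i += 1
                    j -= 1
                loop = j - i + 1
                if run >= min_arm and (max_loop is None or loop <= max_loop):
                    found.append(((a, a + run), (b - run + 1, b + 1), run, loop))
        found.sort(key=lambda t: (t[0][0], -t[2], t[1][0]))
        return found

    return oracle
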