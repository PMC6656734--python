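import numpy as np
import pytest

from mitoarch.gene_orders import GeneOrder
from mitoarch import load_ground_pattern


@pytest.fixture(scope="session")
def ground_pattern() -> GeneOrder:
    return load_ground_pattern()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20190724)


def make_order(text: str, taxon: str = "t") -> GeneOrder:
    """Order from a compact string like 'a b -c d'."""
    toks = []
    for part in text.split():
        sign = -1 if part.startswith("-") else 1
        toks.append((part.lstrip("+-"), sign))
    return GeneOrder.from_tokens(taxon, toks)


def random_signed_order(rng: np.random.Generator, n: int, taxon: str = "t") -> GeneOrder:
    letters = [chr(ord("a") + i) for i in range(n)]
    perm = rng.permutation(n)
    toks = [(letters[int(p)], int(rng.choice([1, -1]))) for p in perm]
    return GeneOrder.from_tokens(taxon, toks)
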