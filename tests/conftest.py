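import numpy as np
import pytest

from hapselect.io import HaplotypeMatrix, RecombinationMap, Variant


def _build_matrix(rows, positions=None, population="TEST"):
    """Matrix from '0'/'1'/'.' strings, one haplotype per row."""
    arr = np.array(
        [[-1 if ch == "." else int(ch) for ch in row] for row in rows],
        dtype=np.int8)
    n_var = arr.shape[1]
    if positions is None:
        positions = [(j + 1) * 1000 for j in range(n_var)]
    variants = [Variant(f"v{j + 1}", "1", int(p), "A", "G")
                for j, p in enumerate(positions)]
    return HaplotypeMatrix(variants, arr, population)


@pytest.fixture
def build_matrix():
    return _build_matrix


@pytest.fixture(scope="session")
def swept_block():
    """A 151-kb, 70-SNP block whose derived-carrier spectrum has counts
    77/9/5/5/4 (P' = 0.77 exactly) plus 50 ancestral chromosomes, with a
    two-point recombination map of 0.0946 cM across the block.

    Returns (matrix, rmap, core_index, block_indices).
    """
    start, end, n_snp = 20_619_001, 20_770_000, 70
    positions = np.round(np.linspace(start, end, n_snp)).astype(int)
    core = n_snp // 2
    founder = np.zeros(n_snp, dtype=np.int8)
    founder[core] = 1
    patterns = [founder]
    for flips in ([3, 4], [10], [20, 21], [50]):
        p = founder.copy()
        p[flips] = 1
        patterns.append(p)
    counts = [77, 9, 5, 5, 4]
    rows = [p for p, c in zip(patterns, counts) for _ in range(c)]
    rows += [np.zeros(n_snp, dtype=np.int8)] * 50
    variants = [Variant(f"snp{j + 1}", "6", int(p), "G", "C")
                for j, p in enumerate(positions)]
    matrix = HaplotypeMatrix(variants, np.stack(rows), "ASN")
    rate = 0.0946 / ((end - start) / 1e6)  # cM/Mb, uniform
    rmap = RecombinationMap([start, end], [rate, rate], [0.0, 0.0946])
    return matrix, rmap, core, (0, n_snp - 1)
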