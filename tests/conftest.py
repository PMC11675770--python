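import numpy as np
import pytest

from tdufe import ExpressionTensor


@pytest.fixture
def small_tensor():
    """Deterministic 5×3×2 tensor with distinct values."""
    rng = np.random.default_rng(42)
    return ExpressionTensor(
        rng.normal(size=(5, 3, 2)),
        feature_ids=[f"g{i}" for i in range(5)],
        sample_labels=["r1", "r2", "r3"],
        slice_labels=["A", "B"],
    )


@pytest.fixture
def expression_tables(tmp_path):
    """Two small TSV expression tables (one per cell line) plus their layout."""
    genes = ["ENSG01", "ENSG02", "ENSG03", "ENSG04", "ENSG05"]
    rng = np.random.default_rng(7)
    paths = []
    layout = {}
    for slice_label in ("A101D", "MeWo"):
        lines = ["gene_id\ts1\ts2"]
        for g in genes:
            v = rng.integers(1, 100, size=2)
            lines.append(f"{g}\t{v[0]}\t{v[1]}")
        p = tmp_path / f"{slice_label}.tsv"
        p.write_text("\n".join(lines) + "\n")
        # each file reuses column names s1/s2 -> disambiguate via per-file copies
        paths.append(p)
    # rewrite with unique column names so one layout covers all four columns
    for p, slice_label in zip(paths, ("A101D", "MeWo")):
        text = p.read_text().replace("s1", f"{slice_label}_s1").replace("s2", f"{slice_label}_s2")
        p.write_text(text)
        layout[f"{slice_label}_s1"] = ("rep1", slice_label)
        layout[f"{slice_label}_s2"] = ("rep2", slice_label)
    return paths, layout


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "SET_A\tfirst set\tG1\tG2\tG3\n"
        "SET_B\tsecond set\tG4\tG5\tG6\tG7\n"
    )
    return path
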