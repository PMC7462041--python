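import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import serkit as sk

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20190803)


@pytest.fixture
def toy_pdb(tmp_path):
    """3-model PDB of a 5-residue Cα-only chain."""
    path = tmp_path / "toy.pdb"
    path.write_text(_make_pdb_text(n_models=3, n_res=5))
    return path


def _make_pdb_text(n_models, n_res, drop_atom_in_model=None):
    rng = np.random.default_rng(7)
    lines = []
    for m in range(1, n_models + 1):
        lines.append(f"MODEL     {m:4d}")
        serial = 0
        for r in range(1, n_res + 1):
            if drop_atom_in_model == m and r == n_res:
                continue
            serial += 1
            x, y, z = rng.uniform(-10, 10, 3)
            lines.append(
                f"ATOM  {serial:5d}  CA  GLY A{r:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def make_pdb(tmp_path):
    def _make(name="x.pdb", n_models=3, n_res=5, drop_atom_in_model=None):
        path = tmp_path / name
        path.write_text(_make_pdb_text(n_models, n_res, drop_atom_in_model))
        return path

    return _make


@pytest.fixture
def small_series():
    """Deterministic 20-row property series for hand-tally checks."""
    rng = np.random.default_rng(11)
    data = pd.DataFrame({
        "Rg": rng.uniform(10.0, 20.0, 20),
        "delta": rng.uniform(0.0, 1.0, 20),
        "Re": rng.uniform(15.0, 45.0, 20),
    })
    return sk.PropertySeries(sequence_id="toy20", n_residues=50, data=data)


@pytest.fixture
def resolved_spec(small_series):
    return sk.make_bins(
        small_series,
        sk.BinSpec(n=4, ranges={"Rg": (10, 20), "delta": (0, 1), "Re": (15, 45)}),
    )


def random_entropy_matrix(rng, spec, sequence_id):
    """Random matrix obeying the entropy bounds for the spec's n."""
    ln_n = np.log(spec.n)
    diag = rng.uniform(0, ln_n, 3)
    off = rng.uniform(0, 2 * ln_n, 3)
    m = np.diag(diag)
    m[0, 1] = m[1, 0] = off[0]
    m[0, 2] = m[2, 0] = off[1]
    m[1, 2] = m[2, 1] = off[2]
    return sk.EnsembleEntropyMatrix(matrix=m, spec=spec, sequence_id=sequence_id)
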