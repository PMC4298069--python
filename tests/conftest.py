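
import pytest

from skinsens import calibrated_published_model, load_fixture


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def calibrated_model():
    """Published model with the full-precision intercept (5.0780)."""
    return calibrated_published_model()


def make_qm_log(occ, virt, charges, dipole=1.234, repeat_eigen=1):
    """Build a minimal Gaussian-style output log for parser tests."""

    def eigen_block(values, kind):
        return f" Alpha {kind} eigenvalues -- " + "".join(
            f"{v:11.5f}" for v in values
        )

    parts = []
    for _ in range(repeat_eigen):
        parts.append(eigen_block(occ, "occ."))
        parts.append(eigen_block(virt, "virt."))
    parts.append(" Mulliken atomic charges:")
    parts.append("               1")
    for i, q in enumerate(charges, 1):
        parts.append(f"    {i:3d}  C  {q:12.6f}")
    parts.append(" Sum of Mulliken atomic charges =   0.00000")
    parts.append(" Dipole moment (field-independent basis, Debye):")
    parts.append(
        f"    X=    0.0000    Y=    0.0000    Z= {dipole:9.4f}  Tot= {dipole:9.4f}"
    )
    return "\n".join(parts) + "\n"


@pytest.fixture
def qm_log_factory(tmp_path):
    def write(name="calc.log", **kwargs):
        path = tmp_path / name
        path.write_text(make_qm_log(**kwargs))
        return path

    return write
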