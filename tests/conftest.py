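import numpy as np
import pytest

from phagescape.pipeline import make_demo_target
from phagescape.targets import TargetSpec


@pytest.fixture(scope="session")
def spec() -> TargetSpec:
    """Synthetic Cas12a-style target: 104-nt amplicon, TTTA PAM + 20-nt protospacer."""
    return make_demo_target()


@pytest.fixture(scope="session")
def cas9_spec() -> TargetSpec:
    """Synthetic Cas9-style target: 3'-side 3-nt PAM, 20-nt protospacer."""
    attempt = 7
    while True:
        rng = np.random.default_rng(attempt)
        ref = "".join(rng.choice(list("ACGT"), size=110))
        try:
            return TargetSpec.from_window(
                amplicon_reference=ref,
                window_start=42,
                pam_side="3prime",
                pam_length=3,
                protospacer_length=20,
                anchor_length=8,
            )
        except Exception:
            attempt += 1


@pytest.fixture(scope="session")
def make_pair():
    """Factory for error-free R1/R2 pairs covering a given window."""
    from phagescape.amplicon import reverse_complement

    def _make(spec: TargetSpec, window: str, read_length: int = 75):
        amplicon = (
            spec.amplicon_reference[: spec.window_start]
            + window
            + spec.amplicon_reference[spec.window_end :]
        )
        r1 = amplicon[:read_length]
        r2 = reverse_complement(amplicon[-read_length:])
        return r1, r2

    return _make
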