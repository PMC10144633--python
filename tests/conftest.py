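import numpy as np
import pytest

from fatiguefusion.fusion import ALERT, FATIGUED, SubjectRecord
from fatiguefusion.keystroke import KeystrokeFeatureVector
from fatiguefusion.thermal import ThermalFeatureVector
from fatiguefusion.visual import VisualFeatureVector
from fatiguefusion.vocal import VocalFeatureVector


def make_record(
    subject_id: str,
    label: int,
    rng: np.random.Generator,
    separation: float = 0.0,
) -> SubjectRecord:
    """Hand-built record whose features shift by ``separation`` sds when fatigued.

    Bypasses artifact rendering entirely — used by fusion/evaluation tests
    that exercise scoring and cross-validation, not extraction.
    """
    s = separation if label == FATIGUED else 0.0

    def v(base, scale=1.0):
        return base + s * scale + rng.normal(0, 1.0) * scale

    return SubjectRecord(
        subject_id=subject_id,
        visual=VisualFeatureVector(
            ECP=abs(v(2.0)), OCOP=1 / 30, COCP=1 / 30, TCT=2 / 30,
            ICFC=abs(v(6.0)), BKC=abs(v(3.0)),
        ),
        thermal=ThermalFeatureVector(
            pixel_count=abs(v(15000, 500)), FHFa=abs(v(1e9, 5e7)),
            FHFr=abs(v(1e9, 5e7)), PRFa=abs(v(9e8, 5e7)), PRFr=abs(v(9e8, 5e7)),
        ),
        keystroke=KeystrokeFeatureVector(
            KSR=abs(v(52.0)), CRE=abs(v(1.0)), AVD=abs(v(5.0)), TST=abs(v(10.0)),
        ),
        vocal=VocalFeatureVector(
            FFP=v(180.0, -3.0), RSH=abs(v(0.5, 0.05)), SPL=v(-9.0),
            PSD=abs(v(0.1, 0.01)), SPD=abs(v(3.0, 0.2)),
        ),
        label=label,
    )


def make_cohort_records(n: int, separation: float, seed: int) -> list[SubjectRecord]:
    rng = np.random.default_rng(seed)
    half = n // 2
    return [
        make_record(f"S{i:03d}", ALERT if i < half else FATIGUED, rng, separation)
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def separable_records() -> list[SubjectRecord]:
    """24 hand-built records with a 5-sd fatigue shift on every feature."""
    return make_cohort_records(24, separation=5.0, seed=42)
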