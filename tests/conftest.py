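import pandas as pd
import pytest

from migessent import (
    EssentialityMatrix,
    GeneAnnotation,
    GeneList,
    GeneUniverse,
)


def make_universe(layout: dict[str, dict]) -> GeneUniverse:
    """Build a GeneUniverse from {symbol: {is_mig, family, age_clade}} shorthand."""
    annotations = {
        sym: GeneAnnotation(
            is_mig=info.get("is_mig", False),
            family=info.get("family"),
            age_clade=info.get("age_clade"),
        )
        for sym, info in layout.items()
    }
    return GeneUniverse(
        interrogated=GeneList(name="test universe", members=tuple(layout)),
        annotations=annotations,
    )


@pytest.fixture
def small_universe() -> GeneUniverse:
    return make_universe(
        {
            "A": {"is_mig": True, "age_clade": "Eukaryota"},
            "B": {"is_mig": False, "age_clade": "Eukaryota"},
            "C": {"is_mig": True, "age_clade": "Metazoa"},
            "D": {"is_mig": False, "age_clade": "Chordata"},
            "E": {"is_mig": False, "age_clade": "Eukaryota"},
            "F": {"is_mig": False, "age_clade": "Bilateria"},
        }
    )


def calls_matrix(data: dict[str, list[float]], genes: list[str]) -> EssentialityMatrix:
    """Calls-mode matrix from {line: per-gene calls} columns."""
    return EssentialityMatrix(values=pd.DataFrame(data, index=genes), mode="calls")
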