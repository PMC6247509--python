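import pytest

from mycoprimer import Oligo, build_pair
from mycoprimer.simulate import (
    FixtureSpec,
    GroupSpec,
    PlantedSite,
    generate_reference_db,
)

# the published best short-amplicon pair (printed sequences; inputs here)
FF390 = "CGATAACGAACGAGACCT"
FR1 = "AICCATTCAATCGGTAIT"


@pytest.fixture(scope="session")
def ff390():
    return Oligo("nu-SSU-1333-5'", FF390, "forward", ref_position=1333)


@pytest.fixture(scope="session")
def fr1():
    return Oligo("nu-SSU-1647-3'", FR1, "reverse", ref_position=1647)


@pytest.fixture(scope="session")
def planted_db(ff390, fr1):
    """100 fungal records with 60 exact + 30 one-substitution sites for each
    primer (dual sites land in the same records by construction) and 20
    outgroup records of which 2 carry exact dual sites."""
    spec = FixtureSpec(
        groups=[
            GroupSpec("Ascomycota", True, 100, subphylum="Pezizomycotina"),
            GroupSpec("Stramenopiles", False, 20),
        ],
        template_length=800,
        planted_sites=[
            PlantedSite(
                ff390, 101,
                {"Ascomycota": {0: 60, 1: 30}, "Stramenopiles": {0: 2}},
            ),
            PlantedSite(
                fr1, 401,
                {"Ascomycota": {0: 60, 1: 30}, "Stramenopiles": {0: 2}},
            ),
        ],
        seed=42,
    )
    return generate_reference_db(spec)


@pytest.fixture(scope="session")
def planted_pair(ff390, fr1):
    return build_pair(ff390, fr1)
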