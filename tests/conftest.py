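import numpy as np
import pandas as pd
import pytest

from isoniche import CommunityConfig, GroupConfig, Stratum, generate_records


@pytest.fixture
def small_records_csv(tmp_path):
    """A 3-row well-formed isotope record table on disk."""
    df = pd.DataFrame(
        {
            "record_id": ["r1", "r2", "r3"],
            "site_id": ["s1", "s1", "s2"],
            "climate_zone": ["temperate", "temperate", "tropical"],
            "land_use": ["woodland", "woodland", "agriculture"],
            "taxon": ["Collembola", "Araneae", "Lumbricina"],
            "family": ["Isotomidae", "", ""],
            "genus": ["", "", ""],
            "species": ["", "", ""],
            "d13C": [-25.1, -23.4, -26.0],
            "d15N": [3.2, 7.7, 2.1],
        }
    )
    path = tmp_path / "records.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture
def one_site_community():
    """One site, one functional group, 3 microbivore taxa x 10 samples."""
    rng = np.random.default_rng(7)
    rows = []
    for taxon, cx, cy in [("Collembola", -25, 4), ("Oribatida", -23, 5), ("Nematoda", -24, 6)]:
        pts = rng.multivariate_normal([cx, cy], np.eye(2), size=10)
        for j, (x, y) in enumerate(pts):
            rows.append(
                dict(
                    record_id=f"{taxon}-{j}",
                    site_id="s1",
                    climate_zone="temperate",
                    land_use="woodland",
                    taxon=taxon,
                    family=f"{taxon}idae",
                    genus="",
                    species="",
                    d13C=x,
                    d15N=y,
                    functional_group="microbivore",
                )
            )
    return pd.DataFrame(rows)


@pytest.fixture
def two_stratum_config():
    """Woodland vs agriculture with a known area multiplier on agriculture."""
    return CommunityConfig(
        strata=(
            Stratum("temperate", "woodland", 30),
            Stratum("temperate", "agriculture", 30),
        ),
        groups={
            "microbivore": GroupConfig(base_centroid=(-24.5, 4.5), taxa_count=4,
                                       samples_per_taxon=(8, 14)),
            "predator": GroupConfig(base_centroid=(-23.5, 7.5), taxa_count=4,
                                    samples_per_taxon=(8, 14)),
        },
        landuse_alpha={"agriculture": 1.5},
        effect_target="both",
        site_sd=0.25,
        seed=11,
    )


@pytest.fixture
def metrics_table(two_stratum_config):
    records, _ = generate_records(two_stratum_config, seed=3)
    from isoniche import compute_site_metrics

    table, _ = compute_site_metrics(records)
    return table
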