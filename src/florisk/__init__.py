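"""florisk: extinction-risk projection and reserve prioritization for
threatened floras censused on ordinal abundance scales.

The package projects per-taxon extinction probabilities by Monte Carlo from
two national censuses recorded in ordinal size classes, assesses how well
protected areas prevent local population decline, and prioritizes map cells
for protection by greedy maximization of the reduction of extinction risk.
"""

from importlib import resources

import pandas as pd

__version__ = "0.1.0"

from .classes import RateClass, SizeClass, class_bounds  # noqa: E402
from .records import (  # noqa: E402
    CellAttributes,
    ChangeEntity,
    PopulationRecord,
    RatePools,
    build_rate_pools,
    read_cell_table,
    read_census_table,
    write_cell_table,
    write_census_table,
)
from .synthetic import (  # noqa: E402
    GroundTruth,
    SyntheticScenario,
    generate_dataset,
    make_worked_fixture,
)
from .pva import (  # noqa: E402
    ExtinctionRiskModel,
    ExtinctionTrajectory,
    PVAResults,
    ScenarioConfig,
    expected_extinction_time,
    run_pva,
)
from .effectiveness import (  # noqa: E402
    DeclineLogit,
    EffectivenessResults,
    label_decline,
    tally_pressures,
)
from .prioritize import (  # noqa: E402
    LocalExtinctionDB,
    PASelection,
    build_local_extinction_db,
    build_local_extinction_dbs,
    complementarity_select,
    compute_rer,
    greedy_select,
    hotspot_select,
    random_select,
    taxon_extinction_cdf,
)
from .workflow import percent_of, run_full_analysis, summarize_rates  # noqa: E402


def load_extinct_redlist() -> pd.DataFrame:
    """The 2012 national Red List taxa recorded Extinct (EX) or Extinct in
    the Wild (EW): 32 + 10 vascular plants."""
    ref = resources.files("florisk") / "data" / "redlist_japan_2012_extinct.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
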