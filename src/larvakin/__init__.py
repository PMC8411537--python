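"""larvakin: comparative kinematics of Drosophila larval crawling.

Per-larva kinematic statistics from tracked trajectories, divergence
clustering of species on 2-D speed x bend-angle distributions, habitat
temperature features from masked climate rasters, classical association
statistics, and Bayesian multivariate Brownian-motion trait evolution on
a fixed phylogeny -- plus synthetic-data generators with known ground
truth for every stage.
"""

from importlib import resources

from . import divergence, habitat, kinematics, phylo, pipeline, stats, synthetic
from .divergence import (
    DivergenceMatrix,
    ProbabilityGrid,
    build_grid,
    divergence_matrix,
    hierarchical_cluster,
    js_divergence,
    kl_divergence,
)
from .habitat import (
    ClimateRaster,
    HabitatTemperature,
    habitat_features,
    mask_values,
    mode_temperature,
    read_ascii_grid,
    temperature_histogram,
    warmest_peak,
    write_ascii_grid,
)
from .kinematics import (
    LarvaKinematics,
    SpeciesKinematics,
    TrackTable,
    centroid_speed,
    extract_species_kinematics,
    filter_tracks,
    kinematic_points,
    label_frames,
    larva_kinematics,
    read_tracks,
    smooth_series,
    species_summary,
    write_tracks,
)
from .phylo import (
    BMParameters,
    BMPosterior,
    MCMCConfig,
    Phylogeny,
    PriorConfig,
    hpd_interval,
    log_likelihood,
    log_prior,
    log_transform_traits,
    phylo_covariance,
    read_newick,
    run_mcmc,
    summarize_posterior,
)
from .stats import (
    CorrelationResult,
    TestResult,
    bonferroni,
    kruskal_wallis,
    mann_whitney_u,
    one_way_anova,
    pearson_with_ci,
    regression_with_band,
)
from .synthetic import (
    FieldSpec,
    GroundTruth,
    SlopeSpec,
    SpeciesBehaviorParams,
    generate_climate_raster,
    make_species_panel,
    simulate_brownian_traits,
    simulate_larva_track,
)

__version__ = "0.1.0"


def fixture_tree_path() -> str:
    """Path to the bundled 11-species tree (synthetic branch lengths)."""
    return str(
        resources.files("larvakin").joinpath("data/drosophila_11sp_synthetic.nwk")
    )
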