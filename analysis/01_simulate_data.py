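"""Generate the synthetic study data: contiguity graph, areal panel,
case registries and provincial denominators.

Emulates the shape of the real study — a national municipality panel of
cervical-cancer case counts among women diagnosed with HIV, with
person-year offsets, decile-coded covariates, and the registry flags
the exclusion cascade and corrections need — at a 10x10-lattice desk
scale. Writes everything under results/data/.
"""

from pathlib import Path

from iccmap.graphs import make_lattice_graph
from iccmap.io import write_graph, write_panel, write_registry
from iccmap.simulate import (
    LinkageConfig,
    SimulationConfig,
    simulate_latent_fields,
    simulate_panel,
    simulate_provincial_denominators,
    simulate_registry,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 20210629


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)  # 10x10 areas, 11 years, 14 age groups
    graph = make_lattice_graph(cfg.n_rows, cfg.n_cols)
    fields = simulate_latent_fields(graph, cfg)
    panel = simulate_panel(graph, fields, cfg)
    registries = simulate_registry(panel, LinkageConfig(seed=SEED + 1))
    provincial, area_counts = simulate_provincial_denominators(
        panel, n_provinces=9, seed=SEED + 2
    )

    write_graph(graph, OUT / "graph.txt")
    write_panel(panel, OUT / "panel.csv")
    write_registry(registries.icc, OUT / "registry_icc.csv")
    write_registry(registries.sentinel, OUT / "registry_sentinel.csv")
    provincial.to_csv(OUT / "provincial_denominators.csv", index=False)
    area_counts.to_csv(OUT / "area_weight_counts.csv", index=False)

    print(f"areas={graph.n} years={cfg.n_years} ages={len(cfg.age_groups)}")
    print(f"total cases={int(panel.y.sum())}, person-years={panel.E.sum():.0f}")
    print(f"registry rows={len(registries.icc)} (linked {registries.icc.linked.mean():.1%})")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
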