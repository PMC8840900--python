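"""Ingest the raw synthetic count tables back into model-ready biomass samples.

Reads the delimited survey written by 01, applies the guild/forest filters,
converts counts to biomass, and checks the bookkeeping invariant that total
biomass is conserved exactly through the split into indicator (titmouse),
target and sample groups.  Writes results/survey/samples_ingested.csv.
"""

from pathlib import Path

from forestbird.ingest import (
    apply_guild_filters,
    build_samples,
    read_locations,
    read_point_counts,
    read_traits,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "survey"
DIALECT = {k: k for k in ("site_id", "point_id", "year", "period",
                          "species_code", "count", "habitat_code")}


def main() -> None:
    table = read_point_counts(OUT / "counts.csv", DIALECT)
    traits = read_traits(OUT / "traits.csv")
    locations = read_locations(OUT / "locations.csv")
    filtered = apply_guild_filters(table, traits)
    samples = build_samples(filtered, traits, locations)
    samples.to_csv(OUT / "samples_ingested.csv", index=False)

    tr = traits.loc[filtered.records["species_code"]]
    total_records = float((filtered.records["count"].to_numpy()
                           * tr["body_mass"].to_numpy()).sum())
    total_samples = float((samples["b"] + samples["tit"]).sum())
    print(f"ingested {len(samples)} point-year samples from {len(table)} count rows")
    print(f"biomass conservation: records {total_records:.1f} g "
          f"vs samples {total_samples:.1f} g "
          f"(difference {abs(total_records - total_samples):.2e} g)")
    n_zero = int((samples['b'] == 0).sum())
    print(f"{n_zero} samples ({100 * n_zero / len(samples):.2f}%) have zero "
          f"forest-bird biomass and will be dropped before gamma fits")


if __name__ == "__main__":
    main()
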