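# Optional supplement exports

The raw study data are distributed only as article supplements and are
not redistributed here. To run the integration tests in
`tests/test_acceptance.py` against them, export the supplements to CSV
in this directory:

- `temperature_insitu.csv` — the in-situ logger series (columns
  `site_id` in {houwan, jialeshui, houbihu}, `timestamp`, `temp_c`).
- `points.csv` — the benthic point records (columns `site_id`, `area`,
  `survey_id` like `2016-10`, `transect`, `photo`, `point`, `otu_id`,
  `bleach_state` in {none, discolored, bleached, not_applicable}).
- `taxonomy.csv` — the OTU table (columns `otu_id`, `label`, `group`,
  `major_category`, `morphotype`, `bleaching_potential`).

When these files are absent the integration tests are skipped; all
other tests run on synthetic data generated at test time.
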