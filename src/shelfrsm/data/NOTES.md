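# Transcription notes for the bundled dataset

The CSVs in this directory transcribe the measured tables of the
storage experiment the package ships as its worked example.  Values
are copied verbatim at their printed precision, with the exceptions
noted below.  Checksums of these files are pinned in the test suite;
any edit here must be recorded in this file.

## Shelf-life designs (`shelf_life_<temperature>_<scheme>.csv`)

One file per residue scheme (OLPR, SCG, OLPR_SCG) and storage
temperature (ambient ~20 C, cold_4C).  Columns: `run_id`, `packaging`
(NONE / PBP / VBP), `rate` (residue fraction, decimal), `response_days`
(measured shelf-life).  The 13 runs cover a 3x3 grid with the
(NONE, rate 0) control replicated five times (runs 1, 10-13).

Rate levels for the combined OLPR/SCG scheme are stored as the printed
decimals 0.17 and 0.33 (not 1/6 and 1/3).

## Total microbial counts (`tmc_<temperature>.csv`)

Long format: `packaging`, `substrate_code` (M1A..M3C: scheme x rate
level, A = wheat-straw control), `temperature`, `day`, `log_cfu_g`.
Ambient days 0-10; cold days 0, 5, 6, 7, 15, 20-24, 27.

### Corrections

* `tmc_ambient.csv`, NONE / M3A / day 6: the source table prints
  `103`, transcribed here as `10.3`.  A value of 103 log CFU/g is
  physically impossible, and 10.3 continues the column trend
  (day 5: 9.2, day 7: 10.9); the reading is an evident decimal-point
  misprint.
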