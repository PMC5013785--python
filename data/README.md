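# Data directory

The original behavioural records of the study this package reanalyses are
distributed as a supplementary word-processor document accompanying the
publication, not as a machine-readable file, and are not redistributed here.

To run the transcription-dependent checks, transcribe the per-odour response
counts into `perez2016_transcribed_responses.csv` in this directory, using
the aggregate CSV schema (comma-separated, UTF-8, header row, `.` decimal
separator):

```
experiment_id,protocol,cs_plus_carbon,cs_minus_carbon,test_carbon,n_tested,n_responders
hexanal+/octanal-,absolute,6,,6,29,29
hexanal+/octanal-,absolute,6,,7,29,27
...
hexanal+/octanal-,differential,6,8,6,38,31
...
```

One row per (experiment, protocol, test odour); `cs_minus_carbon` stays
empty for absolute-conditioning rows; percentages are derived from the
counts, never stored. `gradshift.load_responses` validates the file and the
`gradshift fit`/`compare` subcommands consume it directly.
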