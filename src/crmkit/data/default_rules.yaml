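version: "1.0"
menses_bleeding_fertile: [H, M, L, VL, B]
count_of_three: 3
post_peak_fertile_days: 3
end_of_day_only_post_peak_day: 4
prepeak_dry_end_of_day_only: true
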