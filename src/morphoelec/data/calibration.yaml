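# Reference cohort statistics used to calibrate the synthetic generators.
#
# Each feature entry is a truncated-normal specification {mean, sd, lo, hi}.
# Truncation bounds encode physical plausibility (e.g. positive rheobase,
# spike width achievable at the 10-kHz protocol sampling).
#
# Three groups are profiled: mouse cholinergic and non-cholinergic
# basal-forebrain projection neurons, and macaque cholinergic neurons.
# Electrophysiology and morphology cohort sizes differ because only a
# subset of recorded cells is reconstructed.
version: 1
groups:
  mouse-chol:
    species: mouse
    lineage: cholinergic
    n_ephys: 48
    n_morph: 31
    n_complete: 27
    ephys:
      rmp:              {mean: -54.4, sd: 8.4,  lo: -75.0, hi: -41.0}
      sag:              {mean: 3.0,   sd: 2.0,  lo: 0.3,   hi: 8.0}
      input_resistance: {mean: 250.0, sd: 100.0, lo: 60.0, hi: 600.0}
      tau:              {mean: 34.6,  sd: 14.3, lo: 8.0,   hi: 70.0}
      rheobase:         {mean: 64.3,  sd: 41.2, lo: 10.0,  hi: 190.0}
      spike_threshold:  {mean: -33.0, sd: 4.6,  lo: -48.0, hi: -22.0}
      spike_amplitude:  {mean: 60.0,  sd: 12.0, lo: 35.0,  hi: 90.0}
      spike_width:      {mean: 1.15,  sd: 0.43, lo: 0.5,   hi: 2.6}
      spike_latency:    {mean: 180.0, sd: 90.0, lo: 25.0,  hi: 320.0}
      upstroke:         {mean: 180.0, sd: 60.0, lo: 80.0,  hi: 350.0}
      downstroke:       {mean: -80.0, sd: 25.0, lo: -160.0, hi: -35.0}
      ahp_amplitude:    {mean: 28.9,  sd: 8.3,  lo: 8.0,   hi: 50.0}
      ahp_latency:      {mean: 60.0,  sd: 25.0, lo: 20.0,  hi: 95.0}
      ahp_width:        {mean: 177.9, sd: 89.3, lo: 40.0,  hi: 380.0}
      fi_slope:         {mean: 0.06,  sd: 0.03, lo: 0.01,  hi: 0.2}
      max_rate:         {mean: 7.3,   sd: 4.3,  lo: 2.0,   hi: 30.0}
      adaptation_index: {mean: 0.83,  sd: 0.56, lo: 0.0,   hi: 2.5}
      cv_isi:           {mean: 0.35,  sd: 0.20, lo: 0.02,  hi: 0.9}
    morph:
      n_primary:        {mean: 4.0,   sd: 1.3,  lo: 2.0,   hi: 8.0}
      total_length:     {mean: 1500.0, sd: 700.0, lo: 400.0, hi: 4000.0}
      n_branch_points:  {mean: 8.1,   sd: 5.4,  lo: 0.0,   hi: 25.0}
      total_area:       {mean: 4600.0, sd: 2700.0, lo: 800.0, hi: 15000.0}
      kappa:            {mean: 12.9,  sd: 14.9, lo: 1.0,   hi: 80.0}
      max_extent:       {mean: 105.0, sd: 25.0, lo: 55.0,  hi: 200.0}
      z_scale:          {mean: 0.16,  sd: 0.03, lo: 0.10,  hi: 0.25}
  mouse-nonchol:
    species: mouse
    lineage: non-cholinergic
    n_ephys: 46
    n_morph: 44
    n_complete: 44
    ephys:
      rmp:              {mean: -58.7, sd: 8.2,  lo: -80.0, hi: -41.0}
      sag:              {mean: 3.0,   sd: 2.0,  lo: 0.3,   hi: 8.0}
      input_resistance: {mean: 250.0, sd: 100.0, lo: 60.0, hi: 600.0}
      tau:              {mean: 22.3,  sd: 9.8,  lo: 5.0,   hi: 60.0}
      rheobase:         {mean: 42.2,  sd: 33.2, lo: 10.0,  hi: 190.0}
      spike_threshold:  {mean: -37.1, sd: 6.3,  lo: -52.0, hi: -24.0}
      spike_amplitude:  {mean: 68.0,  sd: 12.0, lo: 40.0,  hi: 95.0}
      spike_width:      {mean: 0.90,  sd: 0.30, lo: 0.45,  hi: 2.0}
      spike_latency:    {mean: 120.0, sd: 70.0, lo: 20.0,  hi: 320.0}
      upstroke:         {mean: 230.0, sd: 70.0, lo: 100.0, hi: 420.0}
      downstroke:       {mean: -110.0, sd: 35.0, lo: -220.0, hi: -45.0}
      ahp_amplitude:    {mean: 12.4,  sd: 6.1,  lo: 2.0,   hi: 35.0}
      ahp_latency:      {mean: 40.0,  sd: 20.0, lo: 15.0,  hi: 90.0}
      ahp_width:        {mean: 85.0,  sd: 118.6, lo: 25.0, hi: 400.0}
      fi_slope:         {mean: 0.25,  sd: 0.15, lo: 0.03,  hi: 0.8}
      max_rate:         {mean: 39.0,  sd: 24.9, lo: 4.0,   hi: 120.0}
      adaptation_index: {mean: 0.64,  sd: 0.29, lo: 0.0,   hi: 2.0}
      cv_isi:           {mean: 0.35,  sd: 0.20, lo: 0.02,  hi: 0.9}
    morph:
      n_primary:        {mean: 4.0,   sd: 1.3,  lo: 2.0,   hi: 8.0}
      total_length:     {mean: 1500.0, sd: 700.0, lo: 400.0, hi: 4000.0}
      n_branch_points:  {mean: 6.6,   sd: 5.4,  lo: 0.0,   hi: 25.0}
      total_area:       {mean: 6600.0, sd: 3600.0, lo: 1000.0, hi: 20000.0}
      kappa:            {mean: 15.2,  sd: 10.1, lo: 1.0,   hi: 80.0}
      max_extent:       {mean: 105.0, sd: 25.0, lo: 55.0,  hi: 200.0}
      z_scale:          {mean: 0.16,  sd: 0.03, lo: 0.10,  hi: 0.25}
  macaque-chol:
    species: macaque
    lineage: cholinergic
    n_ephys: 46
    n_morph: 52
    n_complete: 46
    ephys:
      rmp:              {mean: -58.5, sd: 8.0,  lo: -80.0, hi: -41.0}
      sag:              {mean: 3.0,   sd: 2.0,  lo: 0.3,   hi: 8.0}
      input_resistance: {mean: 380.0, sd: 150.0, lo: 80.0, hi: 800.0}
      tau:              {mean: 45.0,  sd: 16.0, lo: 10.0,  hi: 70.0}
      rheobase:         {mean: 23.3,  sd: 16.5, lo: 10.0,  hi: 90.0}
      spike_threshold:  {mean: -39.7, sd: 5.9,  lo: -55.0, hi: -26.0}
      spike_amplitude:  {mean: 52.0,  sd: 12.0, lo: 30.0,  hi: 85.0}
      spike_width:      {mean: 1.32,  sd: 0.45, lo: 0.55,  hi: 2.8}
      spike_latency:    {mean: 120.0, sd: 70.0, lo: 25.0,  hi: 300.0}
      upstroke:         {mean: 230.0, sd: 75.0, lo: 100.0, hi: 420.0}
      downstroke:       {mean: -80.0, sd: 25.0, lo: -160.0, hi: -35.0}
      ahp_amplitude:    {mean: 19.1,  sd: 8.8,  lo: 4.0,   hi: 45.0}
      ahp_latency:      {mean: 45.0,  sd: 20.0, lo: 15.0,  hi: 90.0}
      ahp_width:        {mean: 106.6, sd: 71.9, lo: 30.0,  hi: 320.0}
      fi_slope:         {mean: 0.13,  sd: 0.10, lo: 0.02,  hi: 0.5}
      max_rate:         {mean: 26.3,  sd: 23.1, lo: 2.0,   hi: 110.0}
      adaptation_index: {mean: 0.85,  sd: 0.50, lo: 0.0,   hi: 2.5}
      cv_isi:           {mean: 0.45,  sd: 0.25, lo: 0.02,  hi: 1.2}
    morph:
      n_primary:        {mean: 5.0,   sd: 1.5,  lo: 2.0,   hi: 9.0}
      total_length:     {mean: 2600.0, sd: 1200.0, lo: 600.0, hi: 6000.0}
      n_branch_points:  {mean: 11.0,  sd: 6.0,  lo: 0.0,   hi: 30.0}
      total_area:       {mean: 9000.0, sd: 4500.0, lo: 1500.0, hi: 25000.0}
      kappa:            {mean: 10.0,  sd: 8.0,  lo: 1.0,   hi: 60.0}
      max_extent:       {mean: 100.0, sd: 25.0, lo: 55.0,  hi: 200.0}
      z_scale:          {mean: 0.90,  sd: 0.05, lo: 0.70,  hi: 1.0}
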