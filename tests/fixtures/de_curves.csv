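quantity,x,value
r_tot_td,100.0,0.001527748862635665
r_tot_td,142.70914972418177,0.0009343549655030598
r_tot_td,203.65901414998953,0.0005645036857389405
r_tot_td,290.6400474301011,0.00033809667749483174
r_tot_td,414.76994044545637,0.00020124963365847527
r_tot_td,591.9146553212059,0.00011927145584744556
r_tot_td,844.7163717017144,7.047001744425071e-05
r_tot_td,1205.4875516364755,4.15464802637827e-05
r_tot_td,1720.3410349712726,2.4457107005436924e-05
r_tot_td,2455.0840633636944,1.4381801714740033e-05
r_tot_td,3503.6295918402207,8.450782326365648e-06
r_tot_td,5000.0,4.963098320314294e-06
mean_zmax_td,100.0,3.6333298899866824
mean_zmax_td,142.70914972418177,4.5162850234315775
mean_zmax_td,203.65901414998953,5.585241677290717
mean_zmax_td,290.6400474301011,6.873877770467067
mean_zmax_td,414.76994044545637,8.422913246776016
mean_zmax_td,591.9146553212059,10.281374943268832
mean_zmax_td,844.7163717017144,12.508131965351442
mean_zmax_td,1205.4875516364755,15.173749506813149
mean_zmax_td,1720.3410349712726,18.3627180894462
mean_zmax_td,2455.0840633636944,22.17612732121642
mean_zmax_td,3503.6295918402207,26.73486781371807
mean_zmax_td,5000.0,32.18346202988778
mean_zmax_cw_rho,10.0,6.113633267855631
mean_zmax_cw_rho,13.894954943731374,7.903834927551688
mean_zmax_cw_rho,19.306977288832496,10.050000899510538
mean_zmax_cw_rho,26.826957952797258,12.584310743545416
mean_zmax_cw_rho,37.2759372031494,15.552924097479048
mean_zmax_cw_rho,51.7947467923121,19.018571852447124
mean_zmax_cw_rho,71.96856730011521,23.062167086054956
mean_zmax_cw_rho,100.0,27.784223110300484
f_td_t1000,1.0,5.1937576687240534e-52
f_td_t1000,4.0,3.414255841632271e-08
f_td_t1000,7.0,0.005526695467600454
f_td_t1000,10.0,0.08247087108263051
f_td_t1000,13.0,0.12493583003789038
f_td_t1000,16.0,0.07944682306812194
f_td_t1000,19.0,0.03083745803791364
f_td_t1000,22.0,0.008210664926894986
f_td_t1000,25.0,0.0015720278766295267
f_td_t1000,28.0,0.00022169499414408664
f_td_t1000,31.0,2.3356647808022253e-05
f_td_t1000,34.0,1.8552211865811167e-06
f_td_t1000,37.0,1.1180127532637093e-07
f_td_t1000,40.0,5.134957003295532e-09
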