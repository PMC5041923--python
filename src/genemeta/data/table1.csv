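study_id,author,year,country,subgroup,case_gg,case_tg,case_tt,control_gg,control_tg,control_tt,reported_association,reported_hwe_p
oskina2013,Natalia A. Oskina,2013,Siberian,white_european,114,186,89,87,177,77,N,0.471
brankovic2013,Ana S. Branković,2013,Serbian,white_european,53,80,17,25,49,26,N,0.842
ho2012,CKM Ho,2012,Scottish,white_european,42,104,70,46,136,66,N,0.102
joung2012,Jae Y. Joung,2012,Korean,east_asian,46,92,56,31,86,51,N,0.618
chan2012,Jason Yongsheng Chan,2012,Chinese,east_asian,63,136,89,23,74,47,N,0.493
liu2009,Miao Liu,2009,Japanese,east_asian,25,151,147,59,181,151,Y,0.694
zheng2007,S. Lilly Zheng,2007,European-American,white_european,495,771,285,142,299,132,Y,0.293
fletcher2008,Olivia Fletcher,2008,English and Scottish,white_european,408,734,338,371,653,312,Y,0.404
cheng2008,Iona Cheng,2008,European-American,white_european,126,215,76,105,206,106,Y,0.807
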